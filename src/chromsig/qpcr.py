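"""RT-qPCR well QC and relative quantification by the 2^-ddCt method.

Plates are plain tables with one row per well: ``plate_id``, ``sample_id``,
``gene``, ``ct`` (threshold cycle, or ``NP`` for no product) and
``melt_ok`` (0/1 flag from melt-curve inspection; an irregular melt peak
indicates non-specific amplification).

Quality control follows fixed rules: wells with irregular melt peaks are
removed; wells with no product, or with Ct strictly greater than the cap
(default 35 cycles), are assigned a sentinel Ct of 40.

Quantification is relative to a reference gene and to the panel itself:

    dCt(s, g)  = Ct(s, g) - Ct(s, reference)
    ddCt(s, g) = dCt(s, g) - mean_s' dCt(s', g)
    fold(s, g) = 2 ** (-ddCt(s, g))

so per-gene fold changes have geometric mean 1 across the samples used in
the centering — expression levels are arbitrary but comparable between
samples.  Technical replicates are averaged on the Ct scale before dCt.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MatrixFormatError

logger = logging.getLogger(__name__)

DEFAULT_CT_CAP = 35.0
DEFAULT_ASSIGNED_CT = 40.0
DEFAULT_REFERENCE_GENE = "B2M"

QC_OK = "ok"
QC_ASSIGNED = "assigned_40"
QC_REMOVED_MELT = "removed_melt"
QC_MISSING_REFERENCE = "missing_reference"

WELL_COLUMNS = ["plate_id", "sample_id", "gene", "ct", "no_product", "melt_ok"]


# ---------------------------------------------------------------------------
# Plate I/O
# ---------------------------------------------------------------------------

def read_plate(path: str | Path) -> pd.DataFrame:
    """Read a plate TSV (columns plate_id, sample_id, gene, ct, melt_ok;
    ct is numeric or ``NP`` for no product)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"plate_id": str, "sample_id": str, "gene": str})
    required = {"plate_id", "sample_id", "gene", "ct", "melt_ok"}
    missing = required - set(df.columns)
    if missing:
        raise MatrixFormatError(f"{path}: missing plate columns {sorted(missing)}")
    ct_raw = df["ct"].astype(str).str.strip()
    no_product = ct_raw.str.upper().eq("NP")
    ct = pd.to_numeric(ct_raw.where(~no_product), errors="coerce")
    bad = (~no_product) & ct.isna()
    if bad.any():
        raise MatrixFormatError(f"{path}: non-numeric ct values at rows {list(df.index[bad][:5])}")
    if (ct.dropna() <= 0).any():
        raise MatrixFormatError(f"{path}: Ct values must be positive")
    out = df[["plate_id", "sample_id", "gene"]].copy()
    out["ct"] = ct
    out["no_product"] = no_product
    out["melt_ok"] = df["melt_ok"].astype(int).astype(bool)
    return out


def write_plate(wells: pd.DataFrame, path: str | Path) -> None:
    """Write wells in the TSV dialect understood by :func:`read_plate`."""
    out = wells[["plate_id", "sample_id", "gene"]].copy()
    ct = wells["ct"].astype(object).copy()
    ct[wells["no_product"]] = "NP"
    out["ct"] = [v if isinstance(v, str) else format(float(v), ".10g") for v in ct]
    out["melt_ok"] = wells["melt_ok"].astype(int)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC and quantification
# ---------------------------------------------------------------------------

def apply_well_qc(
    wells: pd.DataFrame,
    ct_cap: float = DEFAULT_CT_CAP,
    assigned_value: float = DEFAULT_ASSIGNED_CT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply per-well quality control.

    Wells with ``melt_ok`` False are removed; wells with no product or
    ``ct`` strictly greater than ``ct_cap`` get ``ct`` set to
    ``assigned_value``.  A Ct of exactly the cap is untouched.  Returns
    ``(clean_wells, audit)`` where ``audit`` logs the action taken for
    every input well.
    """
    audit = wells.copy()
    audit["qc_status"] = QC_OK

    assigned = wells["no_product"] | (wells["ct"] > ct_cap)
    audit.loc[assigned, "qc_status"] = QC_ASSIGNED
    audit.loc[~wells["melt_ok"], "qc_status"] = QC_REMOVED_MELT

    clean = wells[wells["melt_ok"]].copy()
    clean["qc_status"] = audit.loc[clean.index, "qc_status"]
    hit = clean["qc_status"] == QC_ASSIGNED
    clean.loc[hit, "ct"] = assigned_value
    clean.loc[hit, "no_product"] = False
    n_removed = int((~wells["melt_ok"]).sum())
    if n_removed:
        logger.info("removed %d wells with irregular melt peaks", n_removed)
    if hit.any():
        logger.info("assigned Ct=%g to %d wells (no product or Ct>%g)",
                    assigned_value, int(hit.sum()), ct_cap)
    return clean, audit


def relative_quantification(
    wells: pd.DataFrame,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    include_assigned_in_mean: bool = True,
) -> pd.DataFrame:
    """2^-ddCt quantification of QC'd wells against ``reference_gene``.

    Returns one row per (sample_id, gene) with ``ct_used``, ``delta_ct``,
    ``delta_delta_ct``, ``fold_change`` and ``qc_status``.  Samples where
    the reference gene was not measured get status ``missing_reference``
    and undefined quantities.  ``include_assigned_in_mean=False`` excludes
    sentinel-Ct wells from the per-gene mean dCt (sensitivity analysis;
    the default keeps them, treating the sentinel as a real value).
    """
    if wells.empty:
        return pd.DataFrame(
            columns=["sample_id", "gene", "ct_used", "delta_ct",
                     "delta_delta_ct", "fold_change", "qc_status"]
        )
    if reference_gene not in set(wells["gene"]):
        raise ConfigurationError(
            f"reference gene {reference_gene!r} absent from the plate"
        )
    if "qc_status" not in wells.columns:
        wells = wells.assign(qc_status=QC_OK)

    # Average technical replicates on the Ct scale; a replicate group
    # counts as 'assigned' if any member was.
    agg = (
        wells.groupby(["sample_id", "gene"], sort=True)
        .agg(ct_used=("ct", "mean"),
             assigned=("qc_status", lambda s: bool((s == QC_ASSIGNED).any())))
        .reset_index()
    )

    ref = agg[agg["gene"] == reference_gene].set_index("sample_id")["ct_used"]
    agg["ref_ct"] = agg["sample_id"].map(ref)
    agg["delta_ct"] = agg["ct_used"] - agg["ref_ct"]

    missing_ref = agg["ref_ct"].isna()
    for s in agg.loc[missing_ref, "sample_id"].unique():
        logger.warning("sample %s lacks the reference gene; fold changes undefined", s)

    in_mean = ~missing_ref if include_assigned_in_mean else (~missing_ref & ~agg["assigned"])
    gene_mean = (
        agg[in_mean].groupby("gene")["delta_ct"].mean()
    )
    agg["delta_delta_ct"] = agg["delta_ct"] - agg["gene"].map(gene_mean)
    agg["fold_change"] = np.power(2.0, -agg["delta_delta_ct"])

    agg["qc_status"] = QC_OK
    agg.loc[agg["assigned"], "qc_status"] = QC_ASSIGNED
    agg.loc[missing_ref, "qc_status"] = QC_MISSING_REFERENCE
    return agg[["sample_id", "gene", "ct_used", "delta_ct",
                "delta_delta_ct", "fold_change", "qc_status"]]


def heatmap_scale(
    fold_changes, lo: float = 0.0, hi: float = 10.0
):
    """Clip fold changes to the fixed rendering range [0, 10] with 1 as
    the neutral midpoint; values inside the range pass through unchanged."""
    arr = np.asarray(fold_changes, dtype=float)
    if (arr[np.isfinite(arr)] <= 0).any():
        raise ConfigurationError("fold changes must be positive")
    clipped = np.clip(arr, lo, hi)
    if isinstance(fold_changes, pd.Series):
        return pd.Series(clipped, index=fold_changes.index, name=fold_changes.name)
    return clipped


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.10g")
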