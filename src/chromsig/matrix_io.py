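"""Reading, collapsing and normalizing expression matrices and gene modules.

The on-disk formats are deliberately plain:

* **Matrix TSV** — UTF-8, tab-separated.  First header column is ``id``,
  the remaining header columns are unique sample ids.  An optional second
  header line starting with ``group:`` carries one group label per sample
  (tissue / cancer type).  Probe-level matrices carry a second column
  ``gene`` mapping each probe to its gene symbol.  Empty cells and ``NA``
  are missing values, never zero.
* **GMT** — the standard tab-separated gene-set format:
  ``name <TAB> description <TAB> gene1 <TAB> gene2 ...``.

The processing chain mirrors standard microarray practice: log2-transform
linear intensities, drop unexpressed / discordant probes, collapse probes
to genes by the arithmetic mean, then standardize each gene across samples
(subtract the mean, divide by the standard deviation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    MatrixFormatError,
    ModuleFormatError,
    NormalizationError,
    ParameterError,
)

logger = logging.getLogger(__name__)

LOG2_ABSOLUTE = "log2_absolute"
GENE_NORMALIZED = "gene_normalized"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ProbeMatrix:
    """Probe-level intensity matrix prior to gene collapsing.

    Parameters
    ----------
    values
        probes x samples matrix.  ``scale`` says whether the entries are
        linear intensities or already log2.
    probe_to_gene
        Series indexed by probe id mapping every probe to exactly one
        gene symbol.
    scale
        ``"linear"`` or ``"log2"``.
    sample_groups
        Optional Series mapping sample id -> group label.
    """

    values: pd.DataFrame
    probe_to_gene: pd.Series
    scale: str = "log2"
    sample_groups: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()]
            raise MatrixFormatError(f"duplicate sample ids: {sorted(set(dupes))}")
        if self.values.index.duplicated().any():
            raise MatrixFormatError("duplicate probe ids")
        missing = self.values.index.difference(self.probe_to_gene.index)
        if len(missing):
            raise MatrixFormatError(
                f"{len(missing)} probes lack a gene mapping (e.g. {list(missing[:3])})"
            )
        if self.scale not in ("linear", "log2"):
            raise ParameterError(f"unknown probe-matrix scale {self.scale!r}")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression matrix.

    ``scale`` is ``"log2_absolute"`` (collapsed log2 intensities) or
    ``"gene_normalized"`` (each row centred to mean 0 and scaled to unit
    sample s.d.; rows that were constant are centred only and listed in
    ``constant_genes``).
    """

    values: pd.DataFrame
    scale: str
    sample_groups: pd.Series | None = None
    constant_genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise MatrixFormatError("duplicate gene ids")
        if self.values.columns.duplicated().any():
            raise MatrixFormatError("duplicate sample ids")
        if self.scale not in (LOG2_ABSOLUTE, GENE_NORMALIZED):
            raise ParameterError(f"unknown matrix scale {self.scale!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        if self.sample_groups is None:
            raise ParameterError("matrix carries no sample group annotations")
        hits = [s for s in self.sample_ids if self.sample_groups.get(s) == group]
        if not hits:
            available = sorted(set(self.sample_groups))
            raise ParameterError(
                f"unknown group {group!r}; available groups: {available}"
            )
        return hits


@dataclass(frozen=True)
class GeneModule:
    """A named set of gene symbols, e.g. ChIP-defined enzyme targets."""

    name: str
    genes: frozenset
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ModuleFormatError(f"module {self.name!r} is empty")

    @property
    def size(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# Matrix TSV parsing
# ---------------------------------------------------------------------------

def _parse_cell(text: str) -> float:
    text = text.strip()
    if text == "" or text.upper() in ("NA", "NAN"):
        return np.nan
    try:
        return float(text)
    except ValueError as exc:
        raise MatrixFormatError(f"non-numeric cell {text!r}") from exc


def read_matrix(
    path: str | Path,
    scale: str = LOG2_ABSOLUTE,
) -> ProbeMatrix | ExpressionMatrix:
    """Read a matrix TSV; returns a :class:`ProbeMatrix` when a ``gene``
    mapping column is present, otherwise an :class:`ExpressionMatrix`.

    ``scale`` applies to the returned object: for a probe matrix it must
    be ``"linear"`` or ``"log2"``; for an expression matrix
    ``"log2_absolute"`` or ``"gene_normalized"``.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].strip():
        raise MatrixFormatError(f"{path}: empty file")

    header = lines[0].rstrip("\n").split("\t")
    if header[0] != "id":
        raise MatrixFormatError(f"{path}: first header column must be 'id', got {header[0]!r}")
    has_gene_col = len(header) > 1 and header[1] == "gene"
    first_data_col = 2 if has_gene_col else 1
    sample_ids = header[first_data_col:]
    if not sample_ids:
        raise MatrixFormatError(f"{path}: no sample columns")
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise MatrixFormatError(f"{path}: duplicated sample ids in header: {dupes}")

    groups: pd.Series | None = None
    body_start = 1
    if len(lines) > 1 and lines[1].split("\t", 1)[0] == "group:":
        gfields = lines[1].rstrip("\n").split("\t")
        if len(gfields) != len(header):
            raise MatrixFormatError(
                f"{path}:2: group line has {len(gfields)} fields, expected {len(header)}"
            )
        groups = pd.Series(gfields[first_data_col:], index=sample_ids)
        body_start = 2

    ids: list[str] = []
    gene_map: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[body_start:], start=body_start + 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != len(header):
            raise MatrixFormatError(
                f"{path}:{lineno}: ragged row ({len(fields)} fields, expected {len(header)})"
            )
        ids.append(fields[0])
        if has_gene_col:
            gene_map.append(fields[1])
        try:
            rows.append([_parse_cell(c) for c in fields[first_data_col:]])
        except MatrixFormatError as exc:
            raise MatrixFormatError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise MatrixFormatError(f"{path}: header only, no data rows")

    values = pd.DataFrame(rows, index=ids, columns=sample_ids, dtype=float)
    if has_gene_col:
        return ProbeMatrix(
            values=values,
            probe_to_gene=pd.Series(gene_map, index=ids),
            scale=scale if scale in ("linear", "log2") else "log2",
            sample_groups=groups,
        )
    return ExpressionMatrix(values=values, scale=scale, sample_groups=groups)


def write_matrix(obj: ProbeMatrix | ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix in the TSV dialect understood by :func:`read_matrix`."""
    path = Path(path)
    values = obj.values
    is_probe = isinstance(obj, ProbeMatrix)
    with path.open("w", encoding="utf-8") as fh:
        cols = ["id"] + (["gene"] if is_probe else []) + list(values.columns)
        fh.write("\t".join(cols) + "\n")
        if obj.sample_groups is not None:
            pad = ["group:"] + ([""] if is_probe else [])
            fh.write(
                "\t".join(pad + [str(obj.sample_groups.get(s, "")) for s in values.columns])
                + "\n"
            )
        for rid, row in values.iterrows():
            cells = [str(rid)]
            if is_probe:
                cells.append(str(obj.probe_to_gene.loc[rid]))
            cells.extend("" if np.isnan(v) else format(v, ".10g") for v in row.to_numpy())
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Probe filtering and collapsing
# ---------------------------------------------------------------------------

def _log2_values(pm: ProbeMatrix) -> pd.DataFrame:
    if pm.scale == "log2":
        return pm.values
    vals = pm.values.to_numpy(dtype=float)
    if np.nanmin(vals) <= 0:
        raise ParameterError("linear-scale matrix contains non-positive intensities")
    return pd.DataFrame(np.log2(vals), index=pm.values.index, columns=pm.values.columns)


def filter_probes(
    pm: ProbeMatrix,
    min_interprobe_pcc: float = 0.5,
    drop_unexpressed: bool = True,
    detection_floor: float | None = None,
) -> ProbeMatrix:
    """Drop unexpressed probes and probes discordant with their siblings.

    A probe is *unexpressed* when its value is at or below the detection
    floor in every sample (floor defaults to the matrix minimum).  Among
    probes of the same gene, probes are removed greedily (worst first)
    while any probe's mean Pearson correlation against its siblings falls
    below ``min_interprobe_pcc``; genes with a single probe are never
    touched by the correlation filter, and a discordant two-probe pair is
    kept (no evidence which of the two is at fault).  Filtering operates
    on the log2 scale.
    """
    if not (-1.0 <= min_interprobe_pcc <= 1.0):
        raise ParameterError(
            f"min_interprobe_pcc must be in [-1, 1], got {min_interprobe_pcc}"
        )
    log2 = _log2_values(pm)
    keep = pd.Series(True, index=log2.index)

    if drop_unexpressed:
        floor = detection_floor if detection_floor is not None else np.nanmin(log2.to_numpy())
        unexpressed = (log2 <= floor).all(axis=1) & log2.notna().any(axis=1)
        if unexpressed.any():
            logger.info("dropping %d unexpressed probes", int(unexpressed.sum()))
        keep &= ~unexpressed

    for gene, probes in pm.probe_to_gene[keep].groupby(pm.probe_to_gene[keep]):
        probe_ids = list(probes.index)
        while len(probe_ids) > 2:
            corr = log2.loc[probe_ids].T.corr()  # pairwise-complete PCC
            np.fill_diagonal(corr.values, np.nan)
            mean_pcc = corr.mean(axis=1)  # skips NaN siblings
            worst = mean_pcc.idxmin()
            if np.isnan(mean_pcc.min()) or mean_pcc.min() >= min_interprobe_pcc:
                break
            logger.info(
                "dropping probe %s of gene %s (mean sibling PCC %.3f < %.3f)",
                worst, gene, mean_pcc.min(), min_interprobe_pcc,
            )
            probe_ids.remove(worst)
        dropped = probes.index.difference(probe_ids)
        keep.loc[dropped] = False

    lost_genes = set(pm.probe_to_gene.unique()) - set(pm.probe_to_gene[keep].unique())
    for g in sorted(lost_genes):
        logger.warning("gene %s lost all probes during filtering", g)

    return ProbeMatrix(
        values=pm.values.loc[keep],
        probe_to_gene=pm.probe_to_gene[keep],
        scale=pm.scale,
        sample_groups=pm.sample_groups,
    )


def collapse_probes(pm: ProbeMatrix) -> ExpressionMatrix:
    """Collapse probes to genes by the per-sample arithmetic mean of their
    log2 values (linear input is log2-transformed first)."""
    log2 = _log2_values(pm)
    collapsed = log2.groupby(pm.probe_to_gene).mean()
    collapsed.index.name = None
    return ExpressionMatrix(
        values=collapsed,
        scale=LOG2_ABSOLUTE,
        sample_groups=pm.sample_groups,
    )


def gene_normalize(em: ExpressionMatrix, ddof: int = 1) -> ExpressionMatrix:
    """Standardize each gene across samples: subtract the row mean, divide
    by the row standard deviation (sample s.d., denominator n-1, by
    default).

    Constant rows are centred to zero and recorded in ``constant_genes``
    rather than divided by zero.  Rows with fewer than two observed values
    are set to missing and flagged.  Idempotent on an already normalized
    matrix (flagged rows stay flagged).
    """
    if em.values.shape[1] < 2:
        raise NormalizationError("gene normalization needs at least 2 samples")
    vals = em.values
    n_obs = vals.notna().sum(axis=1)
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=ddof)

    centred = vals.sub(mean, axis=0)
    constant = set(em.constant_genes)
    out = centred.div(sd.replace(0.0, np.nan), axis=0)
    const_mask = (sd == 0.0) & (n_obs >= 2)
    # centred rows are 0 where observed, NaN where missing — keep missingness
    out.loc[const_mask] = centred.loc[const_mask]
    constant |= set(vals.index[const_mask])

    thin = n_obs < 2
    if thin.any():
        out[thin] = np.nan
        constant |= set(vals.index[thin])
        for g in vals.index[thin]:
            logger.warning("gene %s has <2 observed values; normalized row set to missing", g)

    return ExpressionMatrix(
        values=out,
        scale=GENE_NORMALIZED,
        sample_groups=em.sample_groups,
        constant_genes=frozenset(constant),
    )


# ---------------------------------------------------------------------------
# Gene modules (GMT)
# ---------------------------------------------------------------------------

def read_modules(path: str | Path) -> list[GeneModule]:
    """Read gene modules from a GMT file.

    Gene symbols are upper-cased; duplicates within a module are counted
    once (with a warning).  A module line with no genes is an error; a
    file with no lines yields an empty list with a warning.
    """
    path = Path(path)
    modules: list[GeneModule] = []
    lines = [l for l in path.read_text(encoding="utf-8").splitlines() if l.strip()]
    if not lines:
        logger.warning("%s: no modules found", path)
        return modules
    for lineno, line in enumerate(lines, start=1):
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3 or not any(f.strip() for f in fields[2:]):
            raise ModuleFormatError(f"{path}:{lineno}: module {fields[0]!r} has no genes")
        name, description = fields[0], fields[1]
        raw = [f.strip().upper() for f in fields[2:] if f.strip()]
        genes = frozenset(raw)
        if len(genes) < len(raw):
            logger.warning(
                "%s:%d: module %s has %d duplicate gene entries",
                path, lineno, name, len(raw) - len(genes),
            )
        modules.append(GeneModule(name=name, genes=genes, description=description))
    return modules


def write_modules(modules: Iterable[GeneModule], path: str | Path) -> None:
    """Write modules as GMT (genes sorted for reproducible output)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for m in modules:
            fh.write("\t".join([m.name, m.description] + sorted(m.genes)) + "\n")
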