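"""Pearson-correlation signatures between enzyme expression and module
activity, and pairwise gene-gene correlations within sample subsets.

Correlations are computed across samples with pairwise-complete deletion;
the number of complete pairs used for each entry is reported alongside the
coefficient.  An undefined correlation (constant vector, or fewer than
three complete pairs) is reported as missing, never as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import EnrichmentProfile
from .errors import AlignmentError, ParameterError
from .matrix_io import ExpressionMatrix

logger = logging.getLogger(__name__)

MIN_COMPLETE_PAIRS = 3


@dataclass
class CorrelationMatrix:
    """PCC matrix between named entities (genes and/or modules).

    ``pcc`` holds the coefficients, ``n_used`` the pairwise-complete sample
    count behind each entry.  When row and column entities coincide the
    matrix is symmetric with unit diagonal.
    """

    pcc: pd.DataFrame
    n_used: pd.DataFrame
    subset_label: str = ""

    def __post_init__(self) -> None:
        vals = self.pcc.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (np.abs(finite) > 1.0 + 1e-12).any():
            raise ParameterError("PCC values outside [-1, 1]")


def pcc(x, y) -> float:
    """Pearson product-moment correlation on pairwise-complete entries.

    Returns NaN (with a debug-logged reason) when fewer than three complete
    pairs exist or either vector is constant on the complete set.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ParameterError(f"length mismatch: {xa.shape} vs {ya.shape}")
    ok = np.isfinite(xa) & np.isfinite(ya)
    n = int(ok.sum())
    if n < MIN_COMPLETE_PAIRS:
        logger.debug("PCC undefined: only %d complete pairs (<%d)", n, MIN_COMPLETE_PAIRS)
        return np.nan
    xs, ys = xa[ok], ya[ok]
    if np.ptp(xs) == 0.0 or np.ptp(ys) == 0.0:
        logger.debug("PCC undefined: constant vector on the complete set")
        return np.nan
    return float(np.corrcoef(xs, ys)[0, 1])


def _pcc_frame(rows: pd.DataFrame, subset_label: str = "") -> CorrelationMatrix:
    """Symmetric pairwise-complete PCC of the rows of ``rows``."""
    names = list(rows.index)
    k = len(names)
    coef = np.full((k, k), np.nan)
    used = np.zeros((k, k), dtype=int)
    arr = rows.to_numpy(dtype=float)
    finite = np.isfinite(arr)
    for i in range(k):
        coef[i, i] = 1.0
        used[i, i] = int(finite[i].sum())
        for j in range(i + 1, k):
            n = int((finite[i] & finite[j]).sum())
            r = pcc(arr[i], arr[j])
            coef[i, j] = coef[j, i] = r
            used[i, j] = used[j, i] = n
    return CorrelationMatrix(
        pcc=pd.DataFrame(coef, index=names, columns=names),
        n_used=pd.DataFrame(used, index=names, columns=names),
        subset_label=subset_label,
    )


def module_summary_rows(
    profile: EnrichmentProfile,
    em: ExpressionMatrix,
    modules_as: str = "zscore",
) -> pd.DataFrame:
    """Per-sample module summaries: z-score rows (default) or the median
    gene-normalized expression of module genes (``modules_as="median"``).

    The median option needs the module gene sets; it recomputes the median
    from ``em`` restricted to genes behind each module's observed-median
    frame, which the profile already carries.
    """
    if modules_as == "zscore":
        return profile.z.copy()
    if modules_as == "median":
        return profile.observed_median.copy()
    raise ParameterError(f"modules_as must be 'zscore' or 'median', got {modules_as!r}")


def module_enzyme_correlation(
    profile: EnrichmentProfile,
    em: ExpressionMatrix,
    enzymes: Sequence[str],
    modules_as: str = "zscore",
    subset_label: str = "",
) -> CorrelationMatrix:
    """Correlate enzyme expression rows with module activity rows across
    samples (and modules with each other).

    Samples are aligned by id, not position; a sample-set mismatch is an
    error naming the offenders.  Enzymes absent from the matrix are an
    error.  ``modules_as`` selects the module summary: the enrichment
    z-score row (default) or the per-sample median normalized expression.
    """
    em_samples = set(em.sample_ids)
    prof_samples = set(profile.sample_ids)
    if em_samples != prof_samples:
        only_em = sorted(em_samples - prof_samples)
        only_prof = sorted(prof_samples - em_samples)
        raise AlignmentError(
            f"sample sets differ; only in matrix: {only_em[:5]}, "
            f"only in profile: {only_prof[:5]}"
        )
    missing = [g for g in enzymes if g not in em.values.index]
    if missing:
        raise AlignmentError(f"enzymes absent from matrix: {missing}")
    overlap = set(enzymes) & set(profile.module_names)
    if overlap:
        raise ParameterError(f"names used as both enzyme and module: {sorted(overlap)}")

    order = profile.sample_ids
    enzyme_rows = em.values.loc[list(enzymes), order]
    module_rows = module_summary_rows(profile, em, modules_as=modules_as)[order]
    rows = pd.concat([enzyme_rows, module_rows])
    return _pcc_frame(rows, subset_label=subset_label)


def pairwise_gene_correlation(
    em: ExpressionMatrix,
    genes: Sequence[str],
    sample_subset: str | Sequence[str] | None = None,
) -> CorrelationMatrix:
    """Symmetric gene-gene PCC matrix restricted to a sample subset.

    ``sample_subset`` is a group label (resolved through the matrix's
    sample annotations), an explicit list of sample ids, or None for all
    samples.  Needs at least three samples in the subset.
    """
    missing = [g for g in genes if g not in em.values.index]
    if missing:
        raise AlignmentError(f"genes absent from matrix: {missing}")
    if sample_subset is None:
        samples = em.sample_ids
        label = "all"
    elif isinstance(sample_subset, str):
        samples = em.samples_in_group(sample_subset)
        label = sample_subset
    else:
        samples = list(sample_subset)
        unknown = [s for s in samples if s not in em.values.columns]
        if unknown:
            raise AlignmentError(f"samples absent from matrix: {unknown[:5]}")
        label = f"{len(samples)} samples"
    if len(samples) < MIN_COMPLETE_PAIRS:
        logger.warning(
            "subset %r has %d samples (<%d); all off-diagonal PCCs will be missing",
            label, len(samples), MIN_COMPLETE_PAIRS,
        )
    return _pcc_frame(em.values.loc[list(genes), samples], subset_label=label)


def write_correlation(cm: CorrelationMatrix, pcc_path, n_used_path) -> None:
    """Export a correlation matrix and its n_used companion as TSV."""
    cm.pcc.to_csv(pcc_path, sep="\t", index_label="id")
    cm.n_used.to_csv(n_used_path, sep="\t", index_label="id")
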