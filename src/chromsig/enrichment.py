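"""Per-sample gene-module enrichment z-scores against a random-module null.

For one sample, the observed statistic is the median gene-normalized
expression of the module's genes.  The null distribution is the median of
random gene sets of the same (effective) size drawn without replacement
from the genes measured in that sample.  The z-score standardizes the
observed median against the Monte-Carlo null:

    z = (observed_median - null_mean) / null_sd

with ``null_sd`` the population standard deviation of the sampled medians.
Samples where ``z > 1.96`` are called preferentially *over*-expressed for
the module, ``z < -1.96`` *under*-expressed, otherwise not significant.
An exhaustive-enumeration null is provided for small universes as an
oracle and a cross-check.

Seeding: :func:`enrichment_matrix` derives one child seed per
(module, sample) pair from the top-level seed via
``numpy.random.SeedSequence`` spawn keys, so results do not depend on
iteration order and every cell is individually reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .matrix_io import GENE_NORMALIZED, ExpressionMatrix, GeneModule

logger = logging.getLogger(__name__)

Z_THRESHOLD = 1.96
DEFAULT_N_DRAWS = 10_000
EXACT_NULL_CAP = 200_000

CALL_OVER = "over"
CALL_UNDER = "under"
CALL_NS = "ns"


class ModuleZ(NamedTuple):
    """Result of one module x sample z-score evaluation."""

    z: float
    observed_median: float
    null_mean: float
    null_sd: float
    effective_size: int


@dataclass
class EnrichmentProfile:
    """Module x sample enrichment z-scores with significance calls.

    All frames are indexed by module name (rows) and sample id (columns).
    ``call`` holds ``"over"`` / ``"under"`` / ``"ns"`` per the 1.96
    threshold (undefined z is ``"ns"``).
    """

    z: pd.DataFrame
    observed_median: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    call: pd.DataFrame
    effective_sizes: pd.Series
    n_draws: int
    seed: int
    exact: bool = False

    @property
    def module_names(self) -> list[str]:
        return list(self.z.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.z.columns)


def _calls_from_z(z: pd.DataFrame, threshold: float = Z_THRESHOLD) -> pd.DataFrame:
    call = pd.DataFrame(CALL_NS, index=z.index, columns=z.columns)
    call[z > threshold] = CALL_OVER
    call[z < -threshold] = CALL_UNDER
    return call


def _sample_medians(
    values: np.ndarray, size: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Medians of ``n_draws`` random size-``size`` subsets drawn without
    replacement from ``values`` (vectorized via argpartition of uniforms)."""
    n = values.shape[0]
    if size == n:
        return np.full(n_draws, float(np.median(values)))
    keys = rng.random((n_draws, n))
    idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
    return np.median(values[idx], axis=1)


def module_zscore(
    sample_values: pd.Series,
    module: GeneModule,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int | np.random.SeedSequence = 0,
) -> ModuleZ:
    """Monte-Carlo enrichment z-score of one module in one sample.

    ``sample_values`` maps gene -> gene-normalized expression for a single
    sample; missing (NaN) genes are excluded from the universe.  Module
    genes absent from the universe are dropped with a warning and the
    effective size recorded.  If the null is degenerate (``null_sd`` = 0),
    z is 0 when the observed median equals the null mean (e.g. the module
    is the whole universe) and NaN otherwise.
    """
    if n_draws < 1:
        raise ParameterError("n_draws must be >= 1")
    observed = sample_values.dropna()
    present = [g for g in module.genes if g in observed.index]
    n_absent = module.size - len(present)
    if n_absent:
        logger.warning(
            "module %s: %d of %d genes absent from sample; effective size %d",
            module.name, n_absent, module.size, len(present),
        )
    k = len(present)
    if k == 0:
        logger.error("module %s: no genes present in sample, skipping", module.name)
        return ModuleZ(np.nan, np.nan, np.nan, np.nan, 0)

    universe = observed.to_numpy(dtype=float)
    observed_median = float(np.median(observed.loc[present].to_numpy(dtype=float)))

    rng = np.random.default_rng(seed)
    medians = _sample_medians(universe, k, n_draws, rng)
    null_mean = float(medians.mean())
    null_sd = float(medians.std(ddof=0))

    if null_sd == 0.0:
        z = 0.0 if np.isclose(observed_median, null_mean) else np.nan
    else:
        z = (observed_median - null_mean) / null_sd
    return ModuleZ(z, observed_median, null_mean, null_sd, k)


def exact_null(
    sample_values: Sequence[float] | pd.Series,
    module_size: int,
    cap: int = EXACT_NULL_CAP,
) -> tuple[float, float]:
    """Exhaustive null moments: mean and population s.d. of the median over
    every size-``module_size`` subset of the sample's values.

    Refuses when ``C(n, k)`` exceeds ``cap`` (caller falls back to Monte
    Carlo).  This is the unambiguous oracle for :func:`module_zscore`.
    """
    values = np.asarray(
        pd.Series(sample_values).dropna().to_numpy(), dtype=float
    )
    n = values.shape[0]
    if not (1 <= module_size <= n):
        raise ParameterError(f"module_size must be in [1, {n}], got {module_size}")
    n_subsets = comb(n, module_size)
    if n_subsets > cap:
        raise ParameterError(
            f"C({n},{module_size}) = {n_subsets} exceeds the exact-null cap {cap}"
        )
    medians = np.fromiter(
        (np.median(values[list(ix)]) for ix in combinations(range(n), module_size)),
        dtype=float,
        count=n_subsets,
    )
    return float(medians.mean()), float(medians.std(ddof=0))


def exact_zscore(sample_values: pd.Series, module: GeneModule, cap: int = EXACT_NULL_CAP) -> float:
    """z-score against the exhaustive null (small universes only)."""
    observed = sample_values.dropna()
    present = [g for g in module.genes if g in observed.index]
    if not present:
        return np.nan
    obs_median = float(np.median(observed.loc[present].to_numpy(dtype=float)))
    mean, sd = exact_null(observed, len(present), cap=cap)
    if sd == 0.0:
        return 0.0 if np.isclose(obs_median, mean) else np.nan
    return (obs_median - mean) / sd


def enrichment_matrix(
    em: ExpressionMatrix,
    modules: Sequence[GeneModule],
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
    bh_adjust: bool = False,
    bh_alpha: float = 0.05,
) -> EnrichmentProfile:
    """Apply :func:`module_zscore` to every (module, sample) pair.

    The input matrix must be gene-normalized.  With ``bh_adjust`` the
    over/under calls use Benjamini-Hochberg-adjusted two-sided normal
    p-values across the samples of each module instead of the raw 1.96
    threshold (non-default; the raw threshold is the faithful behaviour).
    """
    if em.scale != GENE_NORMALIZED:
        raise ParameterError("enrichment_matrix requires a gene_normalized matrix")
    names = [m.name for m in modules]
    if len(set(names)) != len(names):
        raise ParameterError("duplicate module names")
    samples = em.sample_ids
    shape = (len(modules), len(samples))
    z = np.full(shape, np.nan)
    obs = np.full(shape, np.nan)
    nmean = np.full(shape, np.nan)
    nsd = np.full(shape, np.nan)
    eff = pd.Series(0, index=names, dtype=int)

    for mi, module in enumerate(modules):
        for si, sample in enumerate(samples):
            child = np.random.SeedSequence(entropy=seed, spawn_key=(mi, si))
            res = module_zscore(em.values[sample], module, n_draws=n_draws, seed=child)
            z[mi, si] = res.z
            obs[mi, si] = res.observed_median
            nmean[mi, si] = res.null_mean
            nsd[mi, si] = res.null_sd
            eff[module.name] = res.effective_size

    zf = pd.DataFrame(z, index=names, columns=samples)
    call = _calls_from_z(zf)
    if bh_adjust:
        from scipy.stats import norm
        from statsmodels.stats.multitest import multipletests

        call = pd.DataFrame(CALL_NS, index=zf.index, columns=zf.columns)
        for name in names:
            zr = zf.loc[name]
            ok = zr.notna()
            if not ok.any():
                continue
            p = 2.0 * norm.sf(np.abs(zr[ok].to_numpy()))
            rejected, _, _, _ = multipletests(p, alpha=bh_alpha, method="fdr_bh")
            sig = zr[ok].index[rejected]
            call.loc[name, sig] = np.where(zf.loc[name, sig] > 0, CALL_OVER, CALL_UNDER)

    return EnrichmentProfile(
        z=zf,
        observed_median=pd.DataFrame(obs, index=names, columns=samples),
        null_mean=pd.DataFrame(nmean, index=names, columns=samples),
        null_sd=pd.DataFrame(nsd, index=names, columns=samples),
        call=call,
        effective_sizes=eff,
        n_draws=n_draws,
        seed=seed,
    )


def write_profile(profile: EnrichmentProfile, z_path, calls_path) -> None:
    """Export the z-matrix and the calls matrix as TSV (modules x samples)."""
    profile.z.to_csv(z_path, sep="\t", index_label="module")
    profile.call.to_csv(calls_path, sep="\t", index_label="module")


def read_z_matrix(path) -> pd.DataFrame:
    """Read a z-matrix TSV written by :func:`write_profile`."""
    return pd.read_csv(path, sep="\t", index_col="module")
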