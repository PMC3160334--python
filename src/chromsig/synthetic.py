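"""Synthetic expression matrices, gene modules and qPCR plates with planted
structure.

The expression model is a single latent "enzyme activity" factor per
sample, a_s ~ Normal(group_mean, latent_sd), that drives coupled over- and
under-expression of gene modules on the log2 scale:

    x_gs = baseline_g + beta_m * a_s + eps_gs        (g in module m)
    x_es = baseline_e + loading_e * a_s + eps_es     (e an enzyme gene)
    x_gs = baseline_g + eps_gs                       (background genes)

with eps ~ Normal(0, noise_sd).  Each gene is expanded to its probes by
adding independent Normal(0, probe_noise_sd) probe effects, emulating
multi-probe arrays.  Opposite-signed couplings reproduce the
activating/repressive axis seen between Trithorax-type (e.g. KDM5A-target)
and Polycomb-type (e.g. EZH2-target) modules: the enzyme's expression
correlates positively with its own module and negatively with the
opposing one.

Random streams are partitioned by purpose (module assignment, baselines,
latent factors, gene noise, probe noise) via ``SeedSequence`` children so
changing one rate never perturbs the other draws, and the same scenario +
seed is bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError, SizingError
from .matrix_io import GeneModule, ProbeMatrix

logger = logging.getLogger(__name__)

# Stream ids for SeedSequence spawn keys — stable across releases.
_STREAM_ASSIGN = 0
_STREAM_BASELINE = 1
_STREAM_LATENT = 2
_STREAM_NOISE = 3
_STREAM_PROBE = 4
_STREAM_QPCR_NOISE = 5
_STREAM_QPCR_DROPOUT = 6
_STREAM_QPCR_MELT = 7


@dataclass(frozen=True)
class ModuleSpec:
    """A planted module: ``beta`` is the signed log2 effect per unit of
    latent activity shared by all its genes."""

    name: str
    size: int
    beta: float


@dataclass(frozen=True)
class SyntheticScenario:
    """Full description of a planted-structure expression dataset.

    Defaults emulate a two-module antagonistic axis (an activating
    enzyme's targets coupled +1, a repressive counterpart's targets
    coupled -1) across three sample groups standing in for tissue types.
    Baseline log2 intensities ~ Normal(7, 1.5) match the typical range of
    log2 microarray data.
    """

    n_genes: int = 300
    groups: tuple = (("groupA", 20), ("groupB", 20), ("groupC", 20))
    n_probes_per_gene: int = 1
    modules: tuple = (
        ModuleSpec("KDM5A_TARGETS", 40, +1.0),
        ModuleSpec("EZH2_TARGETS", 40, -1.0),
    )
    enzyme_genes: tuple = (("KDM5A", +1.0), ("EZH2", -1.0))
    latent_group_means: tuple = (("groupA", -2.0), ("groupB", 0.0), ("groupC", +2.0))
    latent_sd: float = 1.0
    noise_sd: float = 0.3
    probe_noise_sd: float = 0.1
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_probes_per_gene < 1:
            raise ParameterError("n_genes and n_probes_per_gene must be positive")
        if self.noise_sd < 0 or self.probe_noise_sd < 0 or self.latent_sd < 0:
            raise ParameterError("standard deviations must be non-negative")
        if any(size < 1 for _, size in self.groups):
            raise ParameterError("group sizes must be positive")
        names = [m.name for m in self.modules]
        if len(set(names)) != len(names):
            raise ParameterError("duplicate module names")
        if sum(m.size for m in self.modules) > self.n_genes:
            raise SizingError(
                f"modules need {sum(m.size for m in self.modules)} genes "
                f"but the universe has {self.n_genes}"
            )
        mean_groups = {g for g, _ in self.latent_group_means}
        missing = [g for g, _ in self.groups if g not in mean_groups]
        if missing:
            raise ParameterError(f"groups lack a latent mean: {missing}")

    @property
    def n_samples(self) -> int:
        return sum(size for _, size in self.groups)


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated dataset."""

    latent_activity: pd.Series          # sample -> a_s
    module_membership: dict             # gene -> module name
    expected_direction: dict            # module name -> +1 / -1 / 0
    group_assignment: pd.Series         # sample -> group label
    modules: list                       # the planted GeneModule objects


def _streams(seed: int, n: int = 8) -> list[np.random.Generator]:
    root = np.random.SeedSequence(seed)
    return [np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
            for i in range(n)]


def generate_expression(scenario: SyntheticScenario) -> tuple[ProbeMatrix, SyntheticTruth]:
    """Generate a probe-level log2 matrix plus its ground truth.

    Enzyme genes are added as extra rows on top of the ``n_genes``
    background universe and never belong to a module.  Deterministic under
    a fixed scenario (same seed -> bit-identical output).
    """
    rngs = _streams(scenario.seed)
    r_assign, r_base, r_latent, r_noise, r_probe = rngs[:5]

    gene_ids = [f"G{i:05d}" for i in range(scenario.n_genes)]
    enzyme_names = [name for name, _ in scenario.enzyme_genes]
    overlap = set(enzyme_names) & set(gene_ids)
    if overlap:
        raise ParameterError(f"enzyme names collide with gene ids: {sorted(overlap)}")
    all_genes = gene_ids + enzyme_names

    # Disjoint module gene sets drawn from the background universe.
    shuffled = list(r_assign.permutation(gene_ids))
    membership: dict[str, str] = {}
    modules: list[GeneModule] = []
    cursor = 0
    for spec in scenario.modules:
        chosen = shuffled[cursor:cursor + spec.size]
        cursor += spec.size
        modules.append(GeneModule(spec.name, frozenset(chosen), "synthetic planted module"))
        membership.update({g: spec.name for g in chosen})

    sample_ids, group_of = [], {}
    for gname, gsize in scenario.groups:
        for i in range(gsize):
            sid = f"{gname}_{i:03d}"
            sample_ids.append(sid)
            group_of[sid] = gname
    group_means = dict(scenario.latent_group_means)
    latent = pd.Series(
        [group_means[group_of[s]] for s in sample_ids], index=sample_ids, dtype=float
    ) + r_latent.normal(0.0, scenario.latent_sd, size=len(sample_ids))

    beta = np.zeros(len(all_genes))
    beta_of_module = {m.name: spec.beta for m, spec in zip(modules, scenario.modules)}
    for gi, g in enumerate(all_genes):
        if g in membership:
            beta[gi] = beta_of_module[membership[g]]
    for name, loading in scenario.enzyme_genes:
        beta[all_genes.index(name)] = loading

    baseline = r_base.normal(scenario.baseline_mean, scenario.baseline_sd, size=len(all_genes))
    noise = r_noise.normal(0.0, scenario.noise_sd, size=(len(all_genes), len(sample_ids)))
    gene_values = baseline[:, None] + np.outer(beta, latent.to_numpy()) + noise

    npp = scenario.n_probes_per_gene
    probe_ids = [f"{g}_p{j}" for g in all_genes for j in range(npp)]
    probe_gene = [g for g in all_genes for _ in range(npp)]
    probe_values = np.repeat(gene_values, npp, axis=0)
    if npp > 1 or scenario.probe_noise_sd > 0:
        probe_values = probe_values + r_probe.normal(
            0.0, scenario.probe_noise_sd, size=probe_values.shape
        )

    pm = ProbeMatrix(
        values=pd.DataFrame(probe_values, index=probe_ids, columns=sample_ids),
        probe_to_gene=pd.Series(probe_gene, index=probe_ids),
        scale="log2",
        sample_groups=pd.Series(group_of),
    )
    truth = SyntheticTruth(
        latent_activity=latent,
        module_membership=membership,
        expected_direction={m.name: int(np.sign(beta_of_module[m.name])) for m in modules},
        group_assignment=pd.Series(group_of).loc[sample_ids],
        modules=modules,
    )
    return pm, truth


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

def generate_qpcr_plate(
    n_samples: int,
    genes: Sequence[str],
    true_fold_changes: Mapping[str, Sequence[float]],
    reference_gene: str = "B2M",
    dropout_rate: float = 0.0,
    melt_fail_rate: float = 0.0,
    seed: int = 0,
    ct_noise_sd: float = 0.0,
    reference_ct: float = 20.0,
    plate_id: str = "P1",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Construct a qPCR plate whose 2^-ddCt analysis recovers known folds.

    ``true_fold_changes`` maps each non-reference gene to its per-sample
    fold change.  Because ddCt centres each gene on its across-sample mean
    dCt, only folds relative to the panel's per-gene geometric mean are
    identifiable; input folds are therefore rescaled to geometric mean 1
    and the rescaled values are the returned truth.  In the noise-free
    case the pipeline recovers them exactly; a fold of 2 lowers a well's
    Ct by exactly one cycle relative to its fold-neutral value.

    Returns ``(wells, truth)``: wells in the plate-table layout and truth
    as a samples x genes fold-change frame.  Dropout wells are emitted
    with the no-product flag; melt-failed wells carry ``melt_ok`` False.
    """
    if reference_gene not in genes:
        raise ConfigurationError(f"reference gene {reference_gene!r} not in gene list")
    for rate, label in ((dropout_rate, "dropout_rate"), (melt_fail_rate, "melt_fail_rate")):
        if not (0.0 <= rate <= 1.0):
            raise ParameterError(f"{label} must be in [0, 1], got {rate}")

    rngs = _streams(seed)
    r_noise, r_drop, r_melt = rngs[_STREAM_QPCR_NOISE], rngs[_STREAM_QPCR_DROPOUT], rngs[_STREAM_QPCR_MELT]

    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    targets = [g for g in genes if g != reference_gene]

    truth = {}
    rows = []
    for gi, gene in enumerate(targets):
        folds = np.asarray(true_fold_changes.get(gene, np.ones(n_samples)), dtype=float)
        if folds.shape != (n_samples,):
            raise ParameterError(f"gene {gene}: need {n_samples} fold values")
        if (folds <= 0).any():
            raise ParameterError(f"gene {gene}: folds must be positive")
        folds = folds / np.exp(np.mean(np.log(folds)))  # geometric mean 1
        truth[gene] = folds
        base_dct = 5.0 + gi  # arbitrary gene-specific offset, cancels in ddCt
        for si, sample in enumerate(sample_ids):
            ct = reference_ct + base_dct - np.log2(folds[si])
            if ct_noise_sd > 0:
                ct += r_noise.normal(0.0, ct_noise_sd)
            rows.append((plate_id, sample, gene, ct))
    for sample in sample_ids:
        ct = reference_ct + (r_noise.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
        rows.append((plate_id, sample, reference_gene, ct))

    wells = pd.DataFrame(rows, columns=["plate_id", "sample_id", "gene", "ct"])
    wells["no_product"] = r_drop.random(len(wells)) < dropout_rate
    wells.loc[wells["no_product"], "ct"] = np.nan
    wells["melt_ok"] = ~(r_melt.random(len(wells)) < melt_fail_rate)

    truth_df = pd.DataFrame(truth, index=sample_ids)
    truth_df.index.name = "sample_id"
    return wells, truth_df
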