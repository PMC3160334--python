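"""Workflow orchestration: the expression-module signature workflow and the
qPCR panel workflow, with config handling and run manifests.

A run is fully determined by its config and seed; the manifest written to
the output directory echoes both plus per-stage dimensions so every output
file is reproducible from the manifest alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import cluster_samples, write_flat_labels, write_newick
from .correlation import (
    module_enzyme_correlation,
    pairwise_gene_correlation,
    write_correlation,
)
from .enrichment import enrichment_matrix, write_profile
from .errors import ConfigurationError
from .matrix_io import (
    ExpressionMatrix,
    ProbeMatrix,
    collapse_probes,
    filter_probes,
    gene_normalize,
    read_matrix,
    read_modules,
    write_matrix,
    write_modules,
)
from .qpcr import (
    DEFAULT_ASSIGNED_CT,
    DEFAULT_CT_CAP,
    DEFAULT_REFERENCE_GENE,
    apply_well_qc,
    heatmap_scale,
    read_plate,
    relative_quantification,
    write_plate,
    write_results,
)
from .synthetic import (
    ModuleSpec,
    SyntheticScenario,
    generate_expression,
    generate_qpcr_plate,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for either workflow.

    Exactly one of ``matrix_path`` / ``scenario`` feeds the signature
    workflow; the qPCR workflow reads ``plate_path`` (or simulates one
    when a scenario-style qPCR block is given).
    """

    # signature workflow inputs
    matrix_path: str | None = None
    modules_path: str | None = None
    scenario: SyntheticScenario | None = None
    enzymes: list = field(default_factory=list)
    # stage options
    min_interprobe_pcc: float = 0.5
    n_draws: int = 10_000
    seed: int = 0
    z_threshold: float = 1.96
    modules_as: str = "zscore"
    linkage_method: str = "average"
    k: int = 3
    cluster_genes: list | None = None
    # qPCR workflow
    plate_path: str | None = None
    reference_gene: str = DEFAULT_REFERENCE_GENE
    ct_cap: float = DEFAULT_CT_CAP
    assigned_ct: float = DEFAULT_ASSIGNED_CT
    # output
    out_dir: str = "chromsig_out"

    def __post_init__(self) -> None:
        if self.matrix_path is not None and self.scenario is not None:
            raise ConfigurationError("give either a matrix file or a scenario, not both")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config.  A ``scenario:`` block becomes a
    :class:`SyntheticScenario`; its ``modules`` entries are
    (name, size, beta) triples and tuples are normalized recursively."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    scenario = None
    if "scenario" in raw:
        s = dict(raw.pop("scenario"))
        if "modules" in s:
            s["modules"] = tuple(ModuleSpec(*m) for m in s["modules"])
        for key in ("groups", "enzyme_genes", "latent_group_means"):
            if key in s:
                s[key] = tuple(tuple(x) for x in s[key])
        scenario = SyntheticScenario(**s)
    return PipelineConfig(scenario=scenario, **raw)


def _manifest(cfg: PipelineConfig, stages: dict) -> dict:
    cfg_dict = asdict(cfg)
    if cfg.scenario is not None:
        cfg_dict["scenario"] = asdict(cfg.scenario)
    return {"chromsig_version": __version__, "config": cfg_dict, "stages": stages}


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )


def run_signature_workflow(cfg: PipelineConfig) -> dict:
    """Read/simulate -> filter -> collapse -> normalize -> enrichment ->
    correlations -> clustering; write all artifacts plus a manifest.

    Returns the manifest dict.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict = {}

    if cfg.scenario is not None:
        pm, truth = generate_expression(cfg.scenario)
        modules = truth.modules
        enzymes = cfg.enzymes or [name for name, _ in cfg.scenario.enzyme_genes]
        write_matrix(pm, out / "probe_matrix.tsv")
        write_modules(modules, out / "modules.gmt")
        truth.latent_activity.rename("latent_activity").to_csv(
            out / "truth_latent.tsv", sep="\t", index_label="sample_id"
        )
        stages["simulate"] = {"n_probes": pm.n_probes, "n_samples": len(pm.sample_ids)}
    else:
        if cfg.matrix_path is None or cfg.modules_path is None:
            raise ConfigurationError("signature workflow needs matrix+modules or a scenario")
        obj = read_matrix(cfg.matrix_path)
        pm = obj if isinstance(obj, ProbeMatrix) else None
        em0 = obj if isinstance(obj, ExpressionMatrix) else None
        modules = read_modules(cfg.modules_path)
        enzymes = list(cfg.enzymes)

    if cfg.scenario is not None or pm is not None:
        pm = filter_probes(pm, min_interprobe_pcc=cfg.min_interprobe_pcc)
        em0 = collapse_probes(pm)
        stages["collapse"] = {"n_genes": len(em0.gene_ids)}
    em = gene_normalize(em0)
    write_matrix(em, out / "normalized_matrix.tsv")
    stages["normalize"] = {
        "n_genes": len(em.gene_ids),
        "n_samples": len(em.sample_ids),
        "n_constant_genes": len(em.constant_genes),
    }

    profile = enrichment_matrix(em, modules, n_draws=cfg.n_draws, seed=cfg.seed)
    write_profile(profile, out / "enrichment_z.tsv", out / "enrichment_calls.tsv")
    stages["enrichment"] = {
        "n_modules": len(modules),
        "n_draws": cfg.n_draws,
        "seed": cfg.seed,
        "effective_sizes": profile.effective_sizes.to_dict(),
    }

    if enzymes:
        cm = module_enzyme_correlation(profile, em, enzymes, modules_as=cfg.modules_as)
        write_correlation(cm, out / "module_enzyme_pcc.tsv", out / "module_enzyme_n.tsv")
        stages["correlation"] = {"entities": list(cm.pcc.index)}
        if em.sample_groups is not None:
            for group in sorted(set(em.sample_groups)):
                if len(em.samples_in_group(group)) < 3:
                    continue
                gm = pairwise_gene_correlation(em, enzymes, sample_subset=group)
                write_correlation(
                    gm,
                    out / f"gene_pcc_{group}.tsv",
                    out / f"gene_pcc_{group}_n.tsv",
                )

    subset = cfg.cluster_genes if cfg.cluster_genes else (enzymes or None)
    clustering = cluster_samples(
        em, gene_subset=subset, linkage_method=cfg.linkage_method, k=cfg.k
    )
    write_newick(clustering, out / "sample_tree.nwk")
    write_flat_labels(clustering, out / "sample_clusters.tsv")
    stages["clustering"] = {
        "k": cfg.k,
        "linkage": cfg.linkage_method,
        "metric": clustering.distance_metric,
        "n_samples": len(clustering.sample_ids),
    }

    manifest = _manifest(cfg, stages)
    _write_manifest(manifest, out)
    return manifest


def run_qpcr_workflow(cfg: PipelineConfig) -> dict:
    """QC -> relative quantification -> heatmap scaling for a plate file.

    Writes the per-well QC audit, the quantification table and the clipped
    heatmap values; raises :class:`ConfigurationError` when nothing
    survives QC so the CLI can exit distinctly on "no data after QC".
    """
    if cfg.plate_path is None:
        raise ConfigurationError("qPCR workflow needs a plate file")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    wells = read_plate(cfg.plate_path)
    clean, audit = apply_well_qc(wells, ct_cap=cfg.ct_cap, assigned_value=cfg.assigned_ct)
    audit_out = audit.copy()
    audit_out["ct"] = audit_out["ct"].map(
        lambda v: "" if pd.isna(v) else format(float(v), ".10g")
    )
    audit_out.to_csv(out / "well_qc_audit.tsv", sep="\t", index=False)
    stages = {
        "qc": {
            "n_wells": len(wells),
            "n_removed_melt": int((audit["qc_status"] == "removed_melt").sum()),
            "n_assigned": int((audit["qc_status"] == "assigned_40").sum()),
        }
    }
    if clean.empty:
        manifest = _manifest(cfg, stages)
        _write_manifest(manifest, out)
        raise ConfigurationError("no wells left after QC; see well_qc_audit.tsv")

    results = relative_quantification(clean, reference_gene=cfg.reference_gene)
    write_results(results, out / "qpcr_results.tsv")
    scaled = results.copy()
    ok = scaled["fold_change"].notna()
    scaled.loc[ok, "fold_change"] = heatmap_scale(scaled.loc[ok, "fold_change"])
    scaled = scaled.rename(columns={"fold_change": "heatmap_value"})
    write_results(
        scaled[["sample_id", "gene", "heatmap_value"]], out / "qpcr_heatmap_scale.tsv"
    )
    stages["quantification"] = {
        "n_results": len(results),
        "reference_gene": cfg.reference_gene,
    }
    manifest = _manifest(cfg, stages)
    _write_manifest(manifest, out)
    return manifest
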