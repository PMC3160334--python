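import numpy as np
import pandas as pd
import pytest

from chromsig import (
    ExpressionMatrix,
    GeneModule,
    ModuleSpec,
    SyntheticScenario,
    collapse_probes,
    filter_probes,
    gene_normalize,
    generate_expression,
)


@pytest.fixture
def small_expression_matrix() -> ExpressionMatrix:
    """5 genes x 4 samples, log2-absolute, with group annotations."""
    values = pd.DataFrame(
        [
            [2.0, 4.0, 6.0, 8.0],
            [1.0, 1.0, 1.0, 1.0],
            [5.0, 3.0, 7.0, 9.0],
            [0.5, 2.5, 4.5, 6.5],
            [10.0, 9.0, 8.0, 7.0],
        ],
        index=["GA", "GB", "GC", "GD", "GE"],
        columns=["s1", "s2", "s3", "s4"],
    )
    groups = pd.Series(["t1", "t1", "t2", "t2"], index=values.columns)
    return ExpressionMatrix(values=values, scale="log2_absolute", sample_groups=groups)


@pytest.fixture
def planted_scenario() -> SyntheticScenario:
    """Antagonistic two-module scenario with one shared latent factor."""
    return SyntheticScenario(
        n_genes=200,
        groups=(("tumA", 30), ("tumB", 30)),
        modules=(
            ModuleSpec("MOD_UP", 30, +1.0),
            ModuleSpec("MOD_DOWN", 30, -1.0),
        ),
        enzyme_genes=(("KDM5A", +1.0),),
        latent_group_means=(("tumA", 0.0), ("tumB", 0.0)),
        latent_sd=1.5,
        noise_sd=0.3,
        probe_noise_sd=0.0,
        seed=11,
    )


@pytest.fixture
def planted_normalized(planted_scenario):
    """Normalized matrix + truth from the planted scenario."""
    pm, truth = generate_expression(planted_scenario)
    em = gene_normalize(collapse_probes(filter_probes(pm)))
    return em, truth


@pytest.fixture
def tiny_module() -> GeneModule:
    return GeneModule("M1", frozenset({"GA", "GC"}), "toy")
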