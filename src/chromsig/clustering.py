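"""Unsupervised hierarchical clustering of samples under the Manhattan
(city-block) distance, with flat-cluster extraction and Newick export.

Samples are clustered on their gene-normalized expression profiles over a
chosen gene subset (typically the chromatin-modifier genes themselves).
Determinism: sample columns are sorted by id before the distance matrix is
built, so the output is exactly invariant to the input column order; ties
in merge height are then resolved by scipy's deterministic scan order over
that sorted layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage, to_tree
from scipy.spatial.distance import pdist

from .errors import AlignmentError, ParameterError
from .matrix_io import GENE_NORMALIZED, ExpressionMatrix

logger = logging.getLogger(__name__)

LINKAGE_METHODS = ("average", "complete", "single")


@dataclass
class ClusteringResult:
    """Agglomerative clustering of samples.

    ``linkage_matrix`` is the scipy (n-1) x 4 merge table over
    ``sample_ids`` (sorted order used for clustering); ``flat_labels``
    maps sample id -> cluster id in 1..k.
    """

    linkage_matrix: np.ndarray
    sample_ids: list[str]
    leaf_order: list[str]
    flat_labels: pd.Series
    k: int
    distance_metric: str = "manhattan"
    linkage_method: str = "average"

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def manhattan_distance(u, v) -> float:
    """City-block distance: sum of absolute coordinate differences over
    pairwise-complete entries.  NaN when no complete pairs exist."""
    ua = np.asarray(u, dtype=float)
    va = np.asarray(v, dtype=float)
    if ua.shape != va.shape:
        raise ParameterError(f"length mismatch: {ua.shape} vs {va.shape}")
    ok = np.isfinite(ua) & np.isfinite(va)
    if not ok.any():
        return np.nan
    return float(np.abs(ua[ok] - va[ok]).sum())


def _distance_matrix(columns: pd.DataFrame) -> np.ndarray:
    """Condensed Manhattan distance over the columns of ``columns``."""
    arr = columns.to_numpy(dtype=float).T  # samples x genes
    if np.isfinite(arr).all():
        return pdist(arr, metric="cityblock")
    n = arr.shape[0]
    out = np.empty(n * (n - 1) // 2)
    pos = 0
    for i in range(n):
        for j in range(i + 1, n):
            out[pos] = manhattan_distance(arr[i], arr[j])
            pos += 1
    if np.isnan(out).any():
        raise ParameterError(
            "some sample pairs share no complete genes; distance undefined"
        )
    return out


def cluster_samples(
    em: ExpressionMatrix,
    gene_subset: Sequence[str] | None = None,
    linkage_method: str = "average",
    k: int = 3,
) -> ClusteringResult:
    """Agglomeratively cluster sample columns under Manhattan distance and
    cut the tree into ``k`` flat clusters.

    ``gene_subset`` restricts the profile to the named genes (all genes
    when None).  The matrix should be gene-normalized so genes contribute
    on comparable scales; a non-normalized matrix is accepted with a
    warning.
    """
    if linkage_method not in LINKAGE_METHODS:
        raise ParameterError(
            f"linkage_method must be one of {LINKAGE_METHODS}, got {linkage_method!r}"
        )
    if em.scale != GENE_NORMALIZED:
        logger.warning("clustering a non-normalized matrix (scale=%s)", em.scale)
    if gene_subset is not None:
        missing = [g for g in gene_subset if g not in em.values.index]
        if missing:
            raise AlignmentError(f"gene_subset genes absent from matrix: {missing}")
        values = em.values.loc[list(gene_subset)]
    else:
        values = em.values
    n_samples = values.shape[1]
    if not (1 <= k <= n_samples):
        raise ParameterError(f"k must be in [1, {n_samples}], got {k}")

    # Sort columns by sample id: determinism independent of input order.
    ordered = sorted(values.columns)
    values = values[ordered]
    condensed = _distance_matrix(values)
    lm = linkage(condensed, method=linkage_method)
    labels = fcluster(lm, t=k, criterion="maxclust")
    leaf_idx = leaves_list(lm)
    return ClusteringResult(
        linkage_matrix=lm,
        sample_ids=ordered,
        leaf_order=[ordered[i] for i in leaf_idx],
        flat_labels=pd.Series(labels, index=ordered, name="cluster"),
        k=k,
        linkage_method=linkage_method,
    )


# ---------------------------------------------------------------------------
# Newick export
# ---------------------------------------------------------------------------

def to_newick(result: ClusteringResult) -> str:
    """Render the merge tree as a Newick string.

    Branch lengths are height differences between a node and its parent
    (leaves sit at height 0), so root-to-leaf path lengths equal merge
    heights — the standard ultrametric dendrogram encoding.
    """
    root = to_tree(result.linkage_matrix)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{result.sample_ids[node.id]}:{length:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return f"({render(root.left, root.dist)},{render(root.right, root.dist)});"


def write_newick(result: ClusteringResult, path: str | Path) -> None:
    Path(path).write_text(to_newick(result) + "\n", encoding="utf-8")


def write_flat_labels(result: ClusteringResult, path: str | Path) -> None:
    result.flat_labels.to_csv(path, sep="\t", index_label="sample_id")
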