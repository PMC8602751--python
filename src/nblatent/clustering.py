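"""Gene-module extraction from the fitted latent embedding.

Genes that are consistently co-expressed across datasets colocate in the
latent space, so modules are simply K-means clusters of the latent rows.
Module scores summarise each module per cell as the mean of log1p
depth-normalised expression over its genes, and weighted Jaccard similarity
compares modules across runs or cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from sklearn.cluster import KMeans

from .types import DatasetCollection, LatentGeneEmbedding

__all__ = [
    "ModuleAssignment",
    "ModuleScoreMatrix",
    "cluster_latent",
    "module_means",
    "weighted_jaccard",
]


@dataclass
class ModuleAssignment:
    """Cluster ids (1..n_clusters) per gene plus the K-means centroids."""

    labels: np.ndarray
    centers: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        self.centers = np.asarray(self.centers, dtype=np.float64)
        n = self.centers.shape[0]
        if self.labels.min(initial=1) < 1 or self.labels.max(initial=1) > n:
            raise ValueError("labels must lie in 1..n_clusters")

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]


@dataclass
class ModuleScoreMatrix:
    """Per dataset: modules x cells matrix of mean module expression."""

    scores: list[np.ndarray]
    dataset_ids: list[str]


def cluster_latent(
    Z: LatentGeneEmbedding, n_clusters: int, seed: int = 0
) -> ModuleAssignment:
    """K-means over latent gene coordinates (k-means++ init, 20 restarts)."""
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if Z.n_genes < n_clusters:
        raise ValueError(f"cannot form {n_clusters} clusters from {Z.n_genes} genes")
    km = KMeans(n_clusters=n_clusters, init="k-means++", n_init=20, random_state=seed)
    labels = km.fit_predict(Z.Z)
    return ModuleAssignment(labels=labels + 1, centers=km.cluster_centers_)


def module_means(x: DatasetCollection, assign: ModuleAssignment) -> ModuleScoreMatrix:
    """Mean log1p depth-normalised expression of each module in each cell."""
    if assign.labels.shape[0] != x.n_genes:
        raise ValueError("one label per gene required")
    scores = []
    for d in x.datasets:
        depth = d.sum(axis=0)
        depth = np.where(depth > 0, depth, 1.0)
        norm = np.log1p(d / depth[None, :] * np.median(depth))
        s = np.vstack(
            [norm[assign.labels == c, :].mean(axis=0) for c in range(1, assign.n_clusters + 1)]
        )
        scores.append(s)
    return ModuleScoreMatrix(scores=scores, dataset_ids=list(x.dataset_ids))


def weighted_jaccard(
    module_a: Mapping[str, float], module_b: Mapping[str, float]
) -> float:
    """Weighted Jaccard similarity of two weighted gene sets.

    ``sum_g min(w_a(g), w_b(g)) / sum_g max(w_a(g), w_b(g))`` over the union
    of genes, absent genes weighted 0. Equals the plain Jaccard index when
    all weights are 0/1.
    """
    union = set(module_a) | set(module_b)
    wa = np.array([float(module_a.get(g, 0.0)) for g in sorted(union)])
    wb = np.array([float(module_b.get(g, 0.0)) for g in sorted(union)])
    if np.any(wa < 0) or np.any(wb < 0):
        raise ValueError("weights must be non-negative")
    denom = np.maximum(wa, wb).sum()
    if denom == 0:
        warnings.warn("both modules have all-zero weights; similarity defined as 0", RuntimeWarning)
        return 0.0
    return float(np.minimum(wa, wb).sum() / denom)


def module_weights(
    x: DatasetCollection, assign: ModuleAssignment, module: int
) -> dict[str, float]:
    """Default weights for weighted Jaccard: a module gene's mean expression
    (log1p depth-normalised, averaged over all cells of the collection)."""
    idx = np.where(assign.labels == module)[0]
    if idx.size == 0:
        raise ValueError(f"module {module} is empty")
    norms = []
    for d in x.datasets:
        depth = d.sum(axis=0)
        depth = np.where(depth > 0, depth, 1.0)
        norms.append(np.log1p(d[idx, :] / depth[None, :] * np.median(depth)))
    mean_expr = np.concatenate(norms, axis=1).mean(axis=1)
    return {x.gene_ids[i]: float(w) for i, w in zip(idx, mean_expr)}
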