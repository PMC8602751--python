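"""Clustering-validity indices and gene-set enrichment.

ARI, Calinski-Harabasz and Davies-Bouldin are delegated to scikit-learn with
explicit handling of the degenerate configurations the library rejects
(zero within-cluster scatter, coincident centroids) via infinity sentinels;
the Dunn index and the hypergeometric enrichment table are implemented here.
Euclidean distance is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from scipy.stats import hypergeom
from sklearn.metrics import (
    adjusted_rand_score,
    calinski_harabasz_score,
    davies_bouldin_score,
)
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PartitionPair",
    "GeneSetCollection",
    "adjusted_rand_index",
    "calinski_harabasz",
    "davies_bouldin",
    "dunn_index",
    "hypergeom_enrich",
]


@dataclass
class PartitionPair:
    labels_a: np.ndarray
    labels_b: np.ndarray

    def __post_init__(self) -> None:
        self.labels_a = np.asarray(self.labels_a).ravel()
        self.labels_b = np.asarray(self.labels_b).ravel()
        if self.labels_a.shape != self.labels_b.shape:
            raise ValueError("partitions must label the same items")
        if self.labels_a.shape[0] < 2:
            raise ValueError("need at least two items")


@dataclass
class GeneSetCollection:
    """Named gene sets over a declared universe."""

    sets: dict[str, set]
    universe: set

    def __post_init__(self) -> None:
        self.universe = set(self.universe)
        self.sets = {name: set(s) for name, s in self.sets.items()}
        for name, s in self.sets.items():
            if not s:
                raise ValueError(f"gene set {name!r} is empty")
            if not s <= self.universe:
                raise ValueError(f"gene set {name!r} is not a subset of the universe")


def adjusted_rand_index(p: PartitionPair) -> float:
    """Chance-adjusted Rand agreement between two partitions."""
    return float(adjusted_rand_score(p.labels_a, p.labels_b))


def _check_points_labels(points, labels):
    points = np.asarray(points, dtype=np.float64)
    labels = np.asarray(labels).ravel()
    if points.ndim == 1:
        points = points[:, None]
    if points.shape[0] != labels.shape[0]:
        raise ValueError("one label per point required")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least two clusters")
    return points, labels, uniq


def calinski_harabasz(points, labels) -> float:
    """CH = [B/(c-1)] / [W/(n-c)]; +inf when within-cluster scatter is zero."""
    points, labels, uniq = _check_points_labels(points, labels)
    W = sum(
        ((points[labels == c] - points[labels == c].mean(axis=0)) ** 2).sum() for c in uniq
    )
    if W == 0.0:
        return float("inf")
    return float(calinski_harabasz_score(points, labels))


def davies_bouldin(points, labels) -> float:
    """Mean over clusters of the worst (s_i + s_j) / d_ij similarity ratio."""
    points, labels, uniq = _check_points_labels(points, labels)
    centroids = np.vstack([points[labels == c].mean(axis=0) for c in uniq])
    if np.any(pdist(centroids) == 0.0):
        return float("inf")
    return float(davies_bouldin_score(points, labels))


def dunn_index(points, labels) -> float:
    """Min inter-cluster point distance over max intra-cluster diameter."""
    points, labels, uniq = _check_points_labels(points, labels)
    diam = 0.0
    for c in uniq:
        pts = points[labels == c]
        if pts.shape[0] > 1:
            diam = max(diam, float(pdist(pts).max()))
    min_inter = np.inf
    for a_idx in range(uniq.size):
        for b_idx in range(a_idx + 1, uniq.size):
            d = cdist(points[labels == uniq[a_idx]], points[labels == uniq[b_idx]])
            min_inter = min(min_inter, float(d.min()))
    if diam == 0.0:
        return float("inf")
    return min_inter / diam


def hypergeom_enrich(module, collection: GeneSetCollection) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a module in each gene set.

    For a universe of size N, a set of size K, a module of size n and an
    overlap of x genes, the p-value is ``P(X >= x)`` for
    ``X ~ Hypergeom(N, K, n)``; p-values are Benjamini-Hochberg adjusted
    across the collection and flagged significant at adjusted p < 0.05.
    """
    module = set(module)
    if not module:
        raise ValueError("module must be non-empty")
    if not module <= collection.universe:
        raise ValueError("module must be a subset of the universe")
    N = len(collection.universe)
    n = len(module)
    rows = []
    for name, s in collection.sets.items():
        x = len(module & s)
        p = float(hypergeom.sf(x - 1, N, len(s), n))
        rows.append({"set": name, "set_size": len(s), "overlap": x, "p": min(p, 1.0)})
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table["significant"] = table["p_adj"] < 0.05
    return table
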