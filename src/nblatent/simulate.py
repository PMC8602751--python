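"""Synthetic scRNA-seq cohorts with ground-truth gene modules.

Two generators cover the study designs every other module is tested against:

* :func:`generate_nb_cohort` — pure negative-binomial cohorts: 9 sets D1..D9
  of increasing dataset count, each dataset 180 genes in three co-expressed
  clusters of 60, counts drawn NB(u_cn, theta_cn) per gene cluster c and
  batch n.
* :func:`generate_splat_cohort` — a gamma-Poisson generative chain in the
  style of the Splat simulator: gamma gene base means, lognormal
  multiplicative batch factors, per-group DE factors defining the
  ground-truth co-expressed groups, lognormal library-size scaling, and a
  logistic dropout mask on the log conditional mean.

Exact per-cluster NB parameters for the pure-NB cohorts are configurable;
the defaults (cluster means {2, 10, 40} with ±20% batch scaling, dispersions
{1, 2, 5}) create clearly separable clusters and are an emulation of the
design, not a replication of any particular dataset. Likewise the
gamma-Poisson defaults make the four DE-driven groups the dominant
co-expression structure (group log-fold-change ~ 2 over a moderate
base-abundance spread), which is the premise of the design: the groups are
meant to be recoverable ground truth even under batch effects and dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import DatasetCollection

__all__ = ["SimulatedCohort", "generate_nb_cohort", "generate_splat_cohort"]

NB_COHORT_REGIMES = {
    # per-cluster base means and dispersions for the two pure-NB cohorts
    1: {"means": (2.0, 10.0, 40.0), "thetas": (1.0, 2.0, 5.0)},
    2: {"means": (4.0, 15.0, 50.0), "thetas": (2.0, 3.0, 8.0)},
}


@dataclass
class SimulatedCohort:
    """Generated datasets plus the ground truth needed to score clustering."""

    collections: list[DatasetCollection]
    true_labels: np.ndarray
    design: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.true_labels = np.asarray(self.true_labels, dtype=int).ravel()
        for coll in self.collections:
            if coll.n_genes != self.true_labels.shape[0]:
                raise ValueError("true_labels must cover every gene of every collection")


def _nb_draw(rng: np.random.Generator, u: float, theta: float, size) -> np.ndarray:
    # numpy's negative_binomial(n, p) has mean n(1-p)/p; n=theta, p=theta/(theta+u)
    return rng.negative_binomial(theta, theta / (theta + u), size=size)


def generate_nb_cohort(
    n_sets: int = 9,
    n_genes: int = 180,
    n_clusters: int = 3,
    cells_per_dataset: int = 200,
    mean_grid: np.ndarray | None = None,
    disp_grid: np.ndarray | None = None,
    seed: int = 0,
    regime: int = 1,
    batch_scale_range: float = 0.2,
) -> SimulatedCohort:
    """Pure-NB cohort of ``n_sets`` sets; set d (1-indexed) holds d datasets.

    Each dataset draws gene i's counts from NB(u_cn, theta_cn) where c is the
    gene's cluster and n the dataset's batch index within the cohort.
    ``mean_grid``/``disp_grid`` are (n_clusters, n_sets) arrays; by default
    the regime's base means are scaled linearly across batches over
    ``1 ± batch_scale_range``.
    """
    if n_genes % n_clusters != 0:
        raise ValueError("n_genes must be divisible by n_clusters")
    if n_sets < 1 or cells_per_dataset < 1:
        raise ValueError("n_sets and cells_per_dataset must be >= 1")
    if mean_grid is None or disp_grid is None:
        base = NB_COHORT_REGIMES[regime]
        if len(base["means"]) != n_clusters:
            raise ValueError("built-in regimes define exactly 3 clusters; pass explicit grids")
        batch_fac = np.linspace(1 - batch_scale_range, 1 + batch_scale_range, n_sets)
        if mean_grid is None:
            mean_grid = np.outer(base["means"], batch_fac)
        if disp_grid is None:
            disp_grid = np.repeat(np.asarray(base["thetas"])[:, None], n_sets, axis=1)
    mean_grid = np.asarray(mean_grid, dtype=np.float64)
    disp_grid = np.asarray(disp_grid, dtype=np.float64)
    if mean_grid.shape != (n_clusters, n_sets) or disp_grid.shape != (n_clusters, n_sets):
        raise ValueError("grids must have shape (n_clusters, n_sets)")
    if np.any(mean_grid <= 0) or np.any(disp_grid <= 0):
        raise ValueError("grids must be strictly positive")

    rng = np.random.default_rng(seed)
    per = n_genes // n_clusters
    labels = np.repeat(np.arange(1, n_clusters + 1), per)
    gene_ids = [f"gene_{i:04d}" for i in range(n_genes)]

    def one_dataset(batch: int) -> np.ndarray:
        mat = np.empty((n_genes, cells_per_dataset))
        for c in range(n_clusters):
            rows = slice(c * per, (c + 1) * per)
            mat[rows, :] = _nb_draw(
                rng, mean_grid[c, batch], disp_grid[c, batch], (per, cells_per_dataset)
            )
        return mat

    collections = []
    for d in range(1, n_sets + 1):
        mats = [one_dataset(batch) for batch in range(d)]
        collections.append(
            DatasetCollection(
                datasets=mats,
                gene_ids=gene_ids,
                dataset_ids=[f"set{d}_batch{b + 1}" for b in range(d)],
            )
        )
    return SimulatedCohort(
        collections=collections,
        true_labels=labels,
        design={
            "style": "nb",
            "n_sets": n_sets,
            "n_genes": n_genes,
            "n_clusters": n_clusters,
            "cells_per_dataset": cells_per_dataset,
            "mean_grid": mean_grid.tolist(),
            "disp_grid": disp_grid.tolist(),
            "seed": seed,
            "regime": regime,
        },
    )


def generate_splat_cohort(
    n_batches: int = 16,
    cells_per_batch: int = 240,
    n_genes: int = 240,
    n_groups: int = 4,
    batch_facloc: float = 1.0,
    batch_facscale: float = 1.0,
    de_prob: float = 1.0,
    de_facloc: float = 2.0,
    de_facscale: float = 0.4,
    dropout_mid: float = 0.0,
    dropout_shape: float = -1.0,
    mean_shape: float = 4.0,
    mean_rate: float = 1.0,
    lib_loc: float = 7.5,
    lib_scale: float = 0.3,
    bcv: float = 0.4,
    seed: int = 0,
    incremental_sets: bool = False,
) -> SimulatedCohort:
    """Gamma-Poisson batches with multiplicative batch factors and dropout.

    The generative chain per batch b and cell j:

    1. gene base means ``g_i ~ Gamma(mean_shape, rate=mean_rate)`` (shared
       across batches);
    2. batch factors ``f_ib ~ LogNormal(batch_facloc, batch_facscale)``
       applied multiplicatively per gene per batch;
    3. each gene belongs to one of ``n_groups`` ground-truth groups; with
       probability ``de_prob`` it receives an up-regulating DE factor
       ``~ LogNormal(de_facloc, de_facscale)`` in cells of its group (cells
       are split evenly across groups), which is what makes group members
       co-expressed;
    4. library sizes ``L_j ~ LogNormal(lib_loc, lib_scale)``; cell means are
       the normalised gene means scaled to ``L_j``;
    5. biological coefficient of variation: the Poisson rate is
       ``Gamma(1/bcv^2, mean=cell_mean)`` (gamma-Poisson == NB);
    6. logistic dropout: each entry is zeroed with probability
       ``sigmoid(dropout_shape * (log(cell_mean) - dropout_mid))``.

    With ``incremental_sets=True`` the cohort exposes sets D1..D(n_batches)
    of increasing batch count (mirroring the pure-NB design); otherwise one
    collection holds all batches.
    """
    if not (0.0 <= de_prob <= 1.0):
        raise ValueError("de_prob must lie in [0, 1]")
    for name, v in [("batch_facscale", batch_facscale), ("lib_scale", lib_scale), ("bcv", bcv)]:
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    if n_genes % n_groups != 0:
        raise ValueError("n_genes must be divisible by n_groups")

    rng = np.random.default_rng(seed)
    per = n_genes // n_groups
    labels = np.repeat(np.arange(1, n_groups + 1), per)
    gene_ids = [f"gene_{i:04d}" for i in range(n_genes)]

    base_mean = rng.gamma(mean_shape, 1.0 / mean_rate, size=n_genes)
    is_de = rng.uniform(size=n_genes) < de_prob
    de_factor = np.where(is_de, rng.lognormal(de_facloc, de_facscale, size=n_genes), 1.0)

    group_of_cell = np.tile(np.arange(1, n_groups + 1), cells_per_batch // n_groups + 1)[
        :cells_per_batch
    ]

    def one_batch() -> np.ndarray:
        batch_fac = rng.lognormal(batch_facloc, batch_facscale, size=n_genes)
        gene_mean = base_mean * batch_fac  # (m,)
        # per-cell group DE: gene i upregulated in cells of its own group
        fac = np.where(labels[:, None] == group_of_cell[None, :], de_factor[:, None], 1.0)
        lib = rng.lognormal(lib_loc, lib_scale, size=cells_per_batch)
        props = gene_mean[:, None] * fac
        props = props / props.sum(axis=0, keepdims=True)
        cell_mean = props * lib[None, :]
        shape = 1.0 / bcv**2
        rate = rng.gamma(shape, cell_mean / shape)
        counts = rng.poisson(rate).astype(float)
        from scipy.special import expit

        # dropout acts on the log conditional mean, not the realised rate
        with np.errstate(divide="ignore"):
            log_mean = np.log(np.maximum(cell_mean, 1e-300))
        p_drop = expit(dropout_shape * (log_mean - dropout_mid))
        counts[rng.uniform(size=counts.shape) < p_drop] = 0.0
        return counts

    batches = [one_batch() for _ in range(n_batches)]
    if incremental_sets:
        collections = [
            DatasetCollection(
                datasets=[batches[b] for b in range(d)],
                gene_ids=gene_ids,
                dataset_ids=[f"set{d}_batch{b + 1}" for b in range(d)],
            )
            for d in range(1, n_batches + 1)
        ]
    else:
        collections = [
            DatasetCollection(
                datasets=batches,
                gene_ids=gene_ids,
                dataset_ids=[f"batch{b + 1}" for b in range(n_batches)],
            )
        ]
    return SimulatedCohort(
        collections=collections,
        true_labels=labels,
        design={
            "style": "splat",
            "n_batches": n_batches,
            "cells_per_batch": cells_per_batch,
            "n_genes": n_genes,
            "n_groups": n_groups,
            "batch_facloc": batch_facloc,
            "batch_facscale": batch_facscale,
            "de_prob": de_prob,
            "de_facloc": de_facloc,
            "de_facscale": de_facscale,
            "dropout_mid": dropout_mid,
            "dropout_shape": dropout_shape,
            "lib_loc": lib_loc,
            "lib_scale": lib_scale,
            "bcv": bcv,
            "seed": seed,
            "incremental_sets": incremental_sets,
        },
    )
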