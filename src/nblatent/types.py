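"""Core in-memory containers for the latent-variable NB co-expression model.

The model views K aligned gene-by-cell count matrices as noisy realisations of
a shared gene-level structure: each gene i carries a latent coordinate
``z_i`` in a lambda-dimensional space (standard-normal prior), while every
cell (j, k) carries an offset ``alpha_jk`` and a loading vector ``beta_jk``
that absorb cell-level technical variation and dataset-level batch effects.
Counts are negative-binomial with conditional mean
``u_ijk = exp(alpha_jk + beta_jk . z_i)`` and gene-by-dataset dispersion
``theta_ik``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DatasetCollection",
    "LatentGeneEmbedding",
    "CellCoefficients",
    "DispersionField",
    "PenaltyWeights",
    "NBParams",
]

#: Ceiling applied to the linear predictor before exponentiation; keeps the
#: exponential link finite on degenerate iterates.
LINK_CLIP = 30.0


def _as_count_matrix(mat, name: str) -> np.ndarray:
    arr = np.asarray(mat, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{name}: expected a 2-D genes x cells matrix, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name}: counts must be finite")
    if np.any(arr < 0):
        raise ValueError(f"{name}: counts must be non-negative")
    rounded = np.rint(arr)
    if np.max(np.abs(arr - rounded), initial=0.0) > 1e-6:
        raise ValueError(f"{name}: counts must be integer-valued (tolerance 1e-6)")
    return rounded


@dataclass
class DatasetCollection:
    """K aligned count matrices sharing one gene index.

    Parameters
    ----------
    datasets
        List of K matrices, each ``m`` genes (rows) by ``n_k`` cells
        (columns), non-negative integer counts.
    gene_ids
        The ``m`` gene identifiers, shared row order across all datasets.
    dataset_ids
        K labels, one per dataset.
    """

    datasets: list[np.ndarray]
    gene_ids: list[str]
    dataset_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.datasets) < 1:
            raise ValueError("need at least one dataset")
        self.datasets = [
            _as_count_matrix(d, f"dataset {idx}") for idx, d in enumerate(self.datasets)
        ]
        self.gene_ids = [str(g) for g in self.gene_ids]
        m = len(self.gene_ids)
        if m < 2:
            raise ValueError("need at least two genes")
        for idx, d in enumerate(self.datasets):
            if d.shape[0] != m:
                raise ValueError(
                    f"dataset {idx} has {d.shape[0]} rows, expected {m} (shared gene index)"
                )
            if d.shape[1] < 1:
                raise ValueError(f"dataset {idx} has no cells")
        if self.dataset_ids is None:
            self.dataset_ids = [f"dataset_{k}" for k in range(len(self.datasets))]
        self.dataset_ids = [str(s) for s in self.dataset_ids]
        if len(self.dataset_ids) != len(self.datasets):
            raise ValueError("dataset_ids length must match number of datasets")
        if len(set(self.dataset_ids)) != len(self.dataset_ids):
            raise ValueError("dataset_ids must be unique")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_datasets(self) -> int:
        return len(self.datasets)

    @property
    def n_cells(self) -> list[int]:
        return [d.shape[1] for d in self.datasets]

    @property
    def total_cells(self) -> int:
        return sum(self.n_cells)

    def subset_genes(self, idx: np.ndarray) -> "DatasetCollection":
        idx = np.asarray(idx)
        return DatasetCollection(
            datasets=[d[idx, :] for d in self.datasets],
            gene_ids=[self.gene_ids[i] for i in idx],
            dataset_ids=list(self.dataset_ids),
        )


@dataclass
class LatentGeneEmbedding:
    """The m x lambda matrix of latent gene coordinates z_i.

    Row i is the coordinate of gene i in the shared latent space; the latent
    dimension doubles as the target module count by convention.
    """

    Z: np.ndarray
    lambda_dim: int = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=np.float64)
        if self.Z.ndim != 2:
            raise ValueError("Z must be an m x lambda matrix")
        if not np.all(np.isfinite(self.Z)):
            raise ValueError("Z entries must be finite")
        if self.lambda_dim is None:
            self.lambda_dim = self.Z.shape[1]
        if self.lambda_dim != self.Z.shape[1]:
            raise ValueError("lambda_dim must equal Z.shape[1]")
        if self.lambda_dim < 1:
            raise ValueError("lambda_dim must be >= 1")

    @property
    def n_genes(self) -> int:
        return self.Z.shape[0]


@dataclass
class CellCoefficients:
    """Per-cell offsets alpha_jk and lambda-vector loadings beta_jk.

    ``alpha[k]`` is an ``(n_k,)`` vector, ``beta[k]`` an ``(n_k, lambda)``
    matrix, one entry per cell of dataset k.
    """

    alpha: list[np.ndarray]
    beta: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.alpha) != len(self.beta):
            raise ValueError("alpha and beta must have one entry per dataset")
        self.alpha = [np.asarray(a, dtype=np.float64).ravel() for a in self.alpha]
        self.beta = [np.atleast_2d(np.asarray(b, dtype=np.float64)) for b in self.beta]
        lam = self.beta[0].shape[1]
        for k, (a, b) in enumerate(zip(self.alpha, self.beta)):
            if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
                raise ValueError(f"non-finite coefficients in dataset {k}")
            if b.shape != (a.shape[0], lam):
                raise ValueError(
                    f"dataset {k}: beta shape {b.shape} incompatible with alpha "
                    f"length {a.shape[0]} and lambda {lam}"
                )

    @property
    def lambda_dim(self) -> int:
        return self.beta[0].shape[1]

    @property
    def n_datasets(self) -> int:
        return len(self.alpha)


@dataclass
class DispersionField:
    """Gene-by-dataset NB dispersions theta_ik (> 0).

    Variance of gene i in dataset k is ``u + u^2 / theta_ik``; a very large
    theta is Poisson-like, a small theta strongly over-dispersed.
    """

    theta: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=np.float64))
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("dispersions must be finite")
        if np.any(self.theta <= 0):
            raise ValueError("dispersions must be strictly positive")


@dataclass
class PenaltyWeights:
    """Per-dataset L1 penalty weights on the cell loadings beta_jk."""

    delta: np.ndarray

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.delta)):
            raise ValueError("penalty weights must be finite")
        if np.any(self.delta < 0):
            raise ValueError("penalty weights must be non-negative")

    @classmethod
    def default(cls, n_datasets: int, lambda_dim: int, n_genes: int, c: float = 1.0):
        """Default rule delta_k = c * sqrt(log(lambda) / m), identical across k."""
        val = c * np.sqrt(np.log(max(lambda_dim, 2)) / n_genes)
        return cls(np.full(n_datasets, val))


@dataclass
class NBParams:
    """Mean/dispersion parameterisation of the negative binomial.

    ``p = u / (u + theta)`` and ``gamma = theta`` give the success-probability
    form; the two parameterisations round-trip exactly.
    """

    u: float
    theta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.u) and self.u > 0):
            raise ValueError("NB mean u must be finite and > 0")
        if not (np.isfinite(self.theta) and self.theta > 0):
            raise ValueError("NB dispersion theta must be finite and > 0")

    @property
    def p(self) -> float:
        return self.u / (self.u + self.theta)

    @property
    def gamma(self) -> float:
        return self.theta

    @classmethod
    def from_pg(cls, p: float, gamma: float) -> "NBParams":
        if not (0.0 < p < 1.0):
            raise ValueError("p must lie in (0, 1)")
        return cls(u=p * gamma / (1.0 - p), theta=gamma)


def canonical_dataset_order(dataset_ids: Sequence[str]) -> list[int]:
    """Indices that sort datasets by id; used wherever accumulation order must
    not depend on the order datasets were supplied in."""
    return sorted(range(len(dataset_ids)), key=lambda k: dataset_ids[k])
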