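"""Likelihood computations for the latent-variable NB model.

All probability mass is computed in log space via ``scipy.special.gammaln``.
The conditional mean of a count given a gene's latent coordinate is
``u = exp(alpha + beta . z)``; the linear predictor is clipped at
``LINK_CLIP`` (= 30) with a warning so degenerate iterates cannot overflow.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import gammaln

from .types import (
    LINK_CLIP,
    CellCoefficients,
    DatasetCollection,
    DispersionField,
    LatentGeneEmbedding,
    NBParams,
    PenaltyWeights,
    canonical_dataset_order,
)

__all__ = [
    "nb_logpmf",
    "nb_logpmf_arrays",
    "nb_mean_var",
    "cell_mean",
    "conditional_loglik",
    "joint_loglik",
    "penalized_loglik",
]


def nb_logpmf(x, params: NBParams) -> float:
    """Log NB pmf at count ``x`` under mean/dispersion ``params``.

    ``f(x; theta, u) = Gamma(x+theta) / (Gamma(theta) Gamma(1+x))
    * (theta/(theta+u))^theta * (u/(theta+u))^x``
    """
    x_arr = np.asarray(x, dtype=np.float64)
    if np.any(x_arr < 0) or np.any(np.rint(x_arr) != x_arr):
        raise ValueError("x must be a non-negative integer")
    return float(nb_logpmf_arrays(x_arr, params.u, params.theta))


def nb_logpmf_arrays(x, u, theta) -> np.ndarray:
    """Vectorised log NB pmf; inputs broadcast. No validation (hot path)."""
    x = np.asarray(x, dtype=np.float64)
    u = np.asarray(u, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    log_ut = np.logaddexp(np.log(u), np.log(theta))  # log(u + theta), stable
    return (
        gammaln(x + theta)
        - gammaln(theta)
        - gammaln(1.0 + x)
        + theta * (np.log(theta) - log_ut)
        + x * (np.log(u) - log_ut)
    )


def nb_mean_var(params: NBParams) -> tuple[float, float]:
    """Mean and variance ``(u, u + u^2/theta)`` of the NB distribution."""
    return params.u, params.u + params.u**2 / params.theta


def cell_mean(alpha: float, beta, z) -> float:
    """Conditional NB mean ``exp(alpha + beta . z)`` for one cell and gene."""
    beta = np.asarray(beta, dtype=np.float64).ravel()
    z = np.asarray(z, dtype=np.float64).ravel()
    if beta.shape != z.shape:
        raise ValueError("beta and z must have equal length")
    eta = float(alpha + beta @ z)
    if eta > LINK_CLIP:
        warnings.warn(
            f"linear predictor {eta:.2f} exceeds clip ceiling {LINK_CLIP}; clipping",
            RuntimeWarning,
            stacklevel=2,
        )
        eta = LINK_CLIP
    return float(np.exp(eta))


def _check_shapes(
    x: DatasetCollection,
    Z: LatentGeneEmbedding,
    coef: CellCoefficients,
    disp: DispersionField,
) -> None:
    m = x.n_genes
    if Z.n_genes != m:
        raise ValueError(f"embedding has {Z.n_genes} genes, counts have {m}")
    if coef.n_datasets != x.n_datasets:
        raise ValueError("coefficients cover a different number of datasets than counts")
    if coef.lambda_dim != Z.lambda_dim:
        raise ValueError("coefficient loading dimension differs from latent dimension")
    if disp.theta.shape != (m, x.n_datasets):
        raise ValueError(
            f"dispersion field shape {disp.theta.shape} != (m, K) = {(m, x.n_datasets)}"
        )
    for k, (a, d) in enumerate(zip(coef.alpha, x.datasets)):
        if a.shape[0] != d.shape[1]:
            raise ValueError(f"dataset {k}: {a.shape[0]} coefficient cells vs {d.shape[1]} count cells")


def _dataset_loglik_per_gene(
    counts: np.ndarray, Z: np.ndarray, alpha: np.ndarray, beta: np.ndarray, theta_col: np.ndarray
) -> np.ndarray:
    """Per-gene summed NB log-likelihood for one dataset (m,) given Z."""
    eta = np.clip(alpha[None, :] + Z @ beta.T, None, LINK_CLIP)
    theta = theta_col[:, None]
    log_ut = np.logaddexp(eta, np.log(theta))
    ll = (
        gammaln(counts + theta)
        - gammaln(theta)
        - gammaln(1.0 + counts)
        + theta * (np.log(theta) - log_ut)
        + counts * (eta - log_ut)
    )
    return ll.sum(axis=1)


def conditional_loglik(
    x: DatasetCollection,
    Z: LatentGeneEmbedding,
    coef: CellCoefficients,
    disp: DispersionField,
) -> float:
    """Sum over all (i, j, k) of the conditional NB log pmf given z_i.

    Accumulated over datasets in sorted-id order so the value (and every
    downstream MCMC decision) is invariant to the order datasets were
    supplied in.
    """
    _check_shapes(x, Z, coef, disp)
    total = np.zeros(x.n_genes)
    for k in canonical_dataset_order(x.dataset_ids):
        total += _dataset_loglik_per_gene(
            x.datasets[k], Z.Z, coef.alpha[k], coef.beta[k], disp.theta[:, k]
        )
    return float(total.sum())


def joint_loglik(
    x: DatasetCollection,
    Z: LatentGeneEmbedding,
    coef: CellCoefficients,
    disp: DispersionField,
) -> float:
    """Conditional log-likelihood plus the standard-normal prior on each z_i."""
    cond = conditional_loglik(x, Z, coef, disp)
    lam = Z.lambda_dim
    prior = -0.5 * float(np.sum(Z.Z**2)) - 0.5 * Z.n_genes * lam * np.log(2.0 * np.pi)
    return cond + prior


def penalized_loglik(
    x: DatasetCollection,
    Z: LatentGeneEmbedding,
    coef: CellCoefficients,
    disp: DispersionField,
    pen: PenaltyWeights,
) -> float:
    """Joint log-likelihood minus the L1 penalty sum_k sum_j delta_k ||beta_jk||_1."""
    if pen.delta.shape[0] != x.n_datasets:
        raise ValueError("one penalty weight per dataset required")
    penalty = sum(
        float(pen.delta[k] * np.abs(coef.beta[k]).sum()) for k in range(x.n_datasets)
    )
    return joint_loglik(x, Z, coef, disp) - penalty
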