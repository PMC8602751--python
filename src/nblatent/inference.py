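"""Monte-Carlo EM for the latent-variable NB model.

The fit alternates two steps until the penalized joint log-likelihood
stabilises:

* **E-step** — for each gene i, a random-walk Metropolis-Hastings chain
  targets the unnormalised posterior ``phi(z_i) * prod_{j,k} f(x_ijk | z_i)``;
  the post-burn-in sample mean replaces the intractable conditional
  expectation (MCEM).
* **M-step** — with Z fixed, every cell's offset ``alpha_jk`` and loading
  ``beta_jk`` solves an L1-penalised NB regression of that cell's counts on Z
  (IRLS with coordinate-wise soft-thresholding; the intercept is never
  penalised), and dispersions ``theta_ik`` are refreshed by method of moments
  on the fitted means.

Both steps are deterministic given the seed, and the M-step never decreases
the penalized objective: the IRLS update is safeguarded by step-halving
against the exact per-cell objective, and a moment dispersion update is kept
only where it improves that (gene, dataset) log-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln
from sklearn.decomposition import PCA

from . import model
from .types import (
    LINK_CLIP,
    CellCoefficients,
    DatasetCollection,
    DispersionField,
    LatentGeneEmbedding,
    PenaltyWeights,
    canonical_dataset_order,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "estimate_dispersion",
    "update_cell_coefficients",
    "sample_latents",
    "fit",
    "select_lambda_bic",
]

THETA_MIN = 1e-2
THETA_MAX = 1e8
ALL_ZERO_CELL_PSEUDOMEAN = 1e-4


@dataclass
class FitConfig:
    """Tuning knobs for the MCEM fit.

    Parameters
    ----------
    lambda_dim
        Latent dimension; doubles as the default module count.
    n_mcmc_samples, mcmc_burnin
        Post-burn-in draws averaged per E-step, and discarded warm-up draws.
    proposal_sd
        Standard deviation of the Gaussian random-walk proposal.
    n_em_iters
        Maximum EM iterations.
    em_tol
        Convergence threshold on the relative change of a 3-iteration moving
        average of the penalized joint log-likelihood, over two consecutive
        iterations.
    delta
        Per-dataset L1 penalty weights; ``None`` selects the default rule
        ``delta_k = sqrt(log(lambda)/m)``.
    rng_seed
        Seed for all Monte-Carlo randomness in the fit.
    """

    lambda_dim: int = 3
    n_mcmc_samples: int = 200
    mcmc_burnin: int = 100
    proposal_sd: float = 0.3
    n_em_iters: int = 50
    em_tol: float = 1e-4
    delta: np.ndarray | None = None
    rng_seed: int = 0
    n_irls_iters: int = 4
    n_cd_passes: int = 8

    def __post_init__(self) -> None:
        if self.lambda_dim < 1:
            raise ValueError("lambda_dim must be >= 1")
        for name in ("n_mcmc_samples", "mcmc_burnin", "n_em_iters", "n_irls_iters", "n_cd_passes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.em_tol <= 0 or self.proposal_sd <= 0:
            raise ValueError("em_tol and proposal_sd must be > 0")


@dataclass
class FitResult:
    """Everything the MCEM fit produces."""

    embedding: LatentGeneEmbedding
    coef: CellCoefficients
    disp: DispersionField
    loglik_trace: list[float]
    converged: bool
    config: FitConfig
    mh_acceptance: float = float("nan")

    @property
    def joint_loglik(self) -> float:
        return self.loglik_trace[-1]


# --------------------------------------------------------------------------
# dispersion


def estimate_dispersion(x: DatasetCollection, means: list[np.ndarray]) -> DispersionField:
    """Method-of-moments dispersions from residual variance around fitted means.

    For gene i in dataset k, with residual second moment
    ``s2 = mean((x - u)^2)`` and mean fitted value ``ubar``, inverts
    ``s2 = ubar + ubar^2/theta`` to ``theta = ubar^2 / (s2 - ubar)``,
    clamped to [1e-2, 1e8]; under-dispersed genes (s2 <= ubar) get the
    Poisson-like ceiling.
    """
    m, K = x.n_genes, x.n_datasets
    theta = np.empty((m, K))
    for k in range(K):
        u = np.asarray(means[k], dtype=np.float64)
        if np.any(u <= 0):
            raise ValueError("fitted means must be strictly positive")
        ubar = u.mean(axis=1)
        s2 = ((x.datasets[k] - u) ** 2).mean(axis=1)
        excess = s2 - ubar
        with np.errstate(divide="ignore", invalid="ignore"):
            est = np.where(excess > 0, ubar**2 / np.where(excess > 0, excess, 1.0), THETA_MAX)
        theta[:, k] = np.clip(est, THETA_MIN, THETA_MAX)
    return DispersionField(theta)


# --------------------------------------------------------------------------
# M-step: per-cell penalized NB regression (vectorised across cells)


def _cells_objective(
    counts: np.ndarray,
    Z: np.ndarray,
    theta_col: np.ndarray,
    alpha: np.ndarray,
    beta: np.ndarray,
    delta_k: float,
) -> np.ndarray:
    """Penalized negative log-likelihood per cell (length n_k).

    Data-only constant terms (gammaln of counts) are included so values are
    comparable across parameter settings but the array is used only for
    per-cell comparisons.
    """
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
    return -ll.sum(axis=0) + delta_k * np.abs(beta).sum(axis=1)


def _update_dataset_coefficients(
    counts: np.ndarray,
    Z: np.ndarray,
    theta_col: np.ndarray,
    delta_k: float,
    alpha0: np.ndarray,
    beta0: np.ndarray,
    n_irls: int,
    n_cd: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Safeguarded IRLS + coordinate descent for every cell of one dataset.

    All cells share the design matrix Z and dispersion column, so the
    coordinate updates vectorise across cells. A step-halving line search
    against the exact per-cell penalized objective guarantees no cell's
    objective increases.
    """
    m, lam = Z.shape
    alpha = alpha0.copy()
    beta = beta0.copy()
    zero_cells = counts.sum(axis=0) == 0
    if np.any(zero_cells):
        warnings.warn(
            f"{int(zero_cells.sum())} all-zero cell(s); intercept floored at "
            f"log({ALL_ZERO_CELL_PSEUDOMEAN})",
            RuntimeWarning,
            stacklevel=3,
        )
    obj = _cells_objective(counts, Z, theta_col, alpha, beta, delta_k)
    theta = theta_col[:, None]
    z_sq = Z**2

    for _ in range(n_irls):
        eta = np.clip(alpha[None, :] + Z @ beta.T, None, LINK_CLIP)
        u = np.exp(eta)
        w = u / (1.0 + u / theta)  # NB working weights, log link
        resid = eta + (counts - u) / u  # working response
        new_alpha = alpha.copy()
        new_beta = beta.copy()
        w_sum = w.sum(axis=0)
        for _ in range(n_cd):
            fit_wo_int = Z @ new_beta.T
            new_alpha = (w * (resid - fit_wo_int)).sum(axis=0) / w_sum
            for l in range(lam):
                partial = resid - new_alpha[None, :] - (Z @ new_beta.T) + np.outer(Z[:, l], new_beta[:, l])
                num = (w * partial * Z[:, l][:, None]).sum(axis=0)
                den = np.maximum((w * z_sq[:, l][:, None]).sum(axis=0), 1e-12)
                new_beta[:, l] = np.sign(num) * np.maximum(np.abs(num) - delta_k, 0.0) / den
        # step-halving toward the IRLS solution, per cell
        step = np.ones(counts.shape[1])
        for _ in range(8):
            trial_alpha = alpha + step * (new_alpha - alpha)
            trial_beta = beta + step[:, None] * (new_beta - beta)
            trial_obj = _cells_objective(counts, Z, theta_col, trial_alpha, trial_beta, delta_k)
            improved = trial_obj <= obj + 1e-10
            alpha = np.where(improved, trial_alpha, alpha)
            beta = np.where(improved[:, None], trial_beta, beta)
            obj = np.where(improved, trial_obj, obj)
            step = np.where(improved, 0.0, step / 2.0)
            if not np.any(step > 0):
                break

    if np.any(zero_cells):
        alpha = np.where(zero_cells, np.log(ALL_ZERO_CELL_PSEUDOMEAN), alpha)
        beta[zero_cells, :] = 0.0
    return alpha, beta


def update_cell_coefficients(
    x_col: np.ndarray,
    Z: LatentGeneEmbedding,
    theta_col: np.ndarray,
    delta_k: float,
    alpha0: float | None = None,
    beta0: np.ndarray | None = None,
    n_irls: int = 8,
    n_cd: int = 10,
) -> tuple[float, np.ndarray]:
    """L1-penalised NB regression of one cell's counts on the latent matrix.

    Returns the minimiser ``(alpha, beta)`` of
    ``-sum_i log f(x_i | theta_i, exp(alpha + beta . z_i)) + delta_k ||beta||_1``.
    """
    x_col = np.asarray(x_col, dtype=np.float64).reshape(-1, 1)
    theta_col = np.asarray(theta_col, dtype=np.float64).ravel()
    if delta_k < 0:
        raise ValueError("penalty weight must be non-negative")
    lam = Z.lambda_dim
    if alpha0 is None:
        alpha0 = float(np.log(max(x_col.mean(), ALL_ZERO_CELL_PSEUDOMEAN)))
    if beta0 is None:
        beta0 = np.zeros(lam)
    a, b = _update_dataset_coefficients(
        x_col,
        Z.Z,
        theta_col,
        float(delta_k),
        np.array([alpha0]),
        np.asarray(beta0, dtype=np.float64).reshape(1, lam),
        n_irls,
        n_cd,
    )
    return float(a[0]), b[0]


# --------------------------------------------------------------------------
# E-step: per-gene random-walk Metropolis-Hastings


def _stack_cells(x: DatasetCollection, coef: CellCoefficients, disp: DispersionField, order):
    """Concatenate per-cell arrays over datasets in canonical order."""
    counts = np.concatenate([x.datasets[k] for k in order], axis=1)
    alpha = np.concatenate([coef.alpha[k] for k in order])
    beta = np.concatenate([coef.beta[k] for k in order], axis=0)
    theta = np.concatenate(
        [np.repeat(disp.theta[:, k][:, None], x.datasets[k].shape[1], axis=1) for k in order],
        axis=1,
    )
    return counts, alpha, beta, theta


def _per_gene_loglik(counts, alpha, beta, theta, log_theta, Z, boundaries) -> np.ndarray:
    """Conditional log-likelihood per gene (m,), data constants dropped.

    Summation runs per dataset block (``boundaries``) and accumulates block
    sums, so the floating-point result is independent of dataset order.
    """
    eta = np.clip(alpha[None, :] + Z @ beta.T, None, LINK_CLIP)
    log_ut = np.logaddexp(eta, log_theta)
    ll = counts * (eta - log_ut) - theta * log_ut
    out = np.zeros(Z.shape[0])
    for lo, hi in boundaries:
        out += ll[:, lo:hi].sum(axis=1)
    return out


def sample_latents(
    x: DatasetCollection,
    coef: CellCoefficients,
    disp: DispersionField,
    Z_current: LatentGeneEmbedding,
    config: FitConfig,
    rng: np.random.Generator | None = None,
    return_draws: bool = False,
):
    """One MCEM E-step: per-gene random-walk MH over the latent posterior.

    Every gene runs an independent chain (proposals are drawn jointly for all
    genes, accept/reject per gene) targeting
    ``phi_lambda(z_i) * prod_{j,k} f(x_ijk | z_i, alpha_jk, beta_jk)``.
    Returns the post-burn-in posterior mean per gene and the average
    acceptance rate (plus the raw post-burn-in draws, shape
    ``(n_mcmc_samples, m, lambda)``, when ``return_draws``). If a chain
    accepts nothing, the proposal sd is halved and the chain re-run once.
    """
    model._check_shapes(x, Z_current, coef, disp)
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    order = canonical_dataset_order(x.dataset_ids)
    counts, alpha, beta, theta = _stack_cells(x, coef, disp, order)
    log_theta = np.log(theta)
    sizes = [x.datasets[k].shape[1] for k in order]
    bounds = []
    lo = 0
    for s in sizes:
        bounds.append((lo, lo + s))
        lo += s

    def run_chain(sd: np.ndarray, collect: bool):
        m, lam = Z_current.Z.shape
        n_steps = config.mcmc_burnin + config.n_mcmc_samples
        Z = Z_current.Z.copy()
        logp = _per_gene_loglik(counts, alpha, beta, theta, log_theta, Z, bounds) - 0.5 * (
            Z**2
        ).sum(axis=1)
        mean_acc = np.zeros(m)
        Z_sum = np.zeros_like(Z)
        kept = np.empty((config.n_mcmc_samples, m, lam)) if collect else None
        n_kept = 0
        for t in range(n_steps):
            prop = Z + rng.normal(0.0, 1.0, size=Z.shape) * sd[:, None]
            logp_prop = _per_gene_loglik(
                counts, alpha, beta, theta, log_theta, prop, bounds
            ) - 0.5 * (prop**2).sum(axis=1)
            accept = np.log(rng.uniform(size=m)) < (logp_prop - logp)
            Z = np.where(accept[:, None], prop, Z)
            logp = np.where(accept, logp_prop, logp)
            mean_acc += accept
            if t >= config.mcmc_burnin:
                Z_sum += Z
                if collect:
                    kept[n_kept] = Z
                n_kept += 1
        return Z_sum / n_kept, mean_acc / n_steps, kept

    sd = np.full(Z_current.n_genes, config.proposal_sd)
    Z_mean, acc, kept = run_chain(sd, return_draws)
    dead = acc == 0.0
    if np.any(dead):
        warnings.warn(
            f"{int(dead.sum())} gene chain(s) accepted no proposal; halving proposal sd and re-running once",
            RuntimeWarning,
            stacklevel=2,
        )
        Z_retry, acc_retry, kept_retry = run_chain(np.where(dead, sd / 2.0, sd), return_draws)
        Z_mean = np.where(dead[:, None], Z_retry, Z_mean)
        acc = np.where(dead, acc_retry, acc)
        if return_draws:
            kept = np.where(dead[None, :, None], kept_retry, kept)
    if return_draws:
        return LatentGeneEmbedding(Z_mean), float(acc.mean()), kept
    return LatentGeneEmbedding(Z_mean), float(acc.mean())


# --------------------------------------------------------------------------
# initialisation and the EM driver


def _initial_embedding(x: DatasetCollection, lambda_dim: int, seed: int) -> LatentGeneEmbedding:
    """PCA of log1p depth-normalised, gene-standardised concatenated counts."""
    order = canonical_dataset_order(x.dataset_ids)
    mats = []
    for k in order:
        d = x.datasets[k]
        depth = d.sum(axis=0)
        depth = np.where(depth > 0, depth, 1.0)
        mats.append(np.log1p(d / depth[None, :] * np.median(depth)))
    concat = np.concatenate(mats, axis=1)
    mu = concat.mean(axis=1, keepdims=True)
    sd = concat.std(axis=1, keepdims=True)
    concat = (concat - mu) / np.where(sd > 0, sd, 1.0)
    n_comp = min(lambda_dim, x.n_genes - 1, concat.shape[1])
    pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(concat)
    if n_comp < lambda_dim:
        pcs = np.pad(pcs, ((0, 0), (0, lambda_dim - n_comp)))
    scale = pcs.std(axis=0)
    pcs = pcs / np.where(scale > 0, scale, 1.0)
    return LatentGeneEmbedding(pcs)


def _resolve_penalty(x: DatasetCollection, config: FitConfig) -> PenaltyWeights:
    if config.delta is not None:
        delta = np.asarray(config.delta, dtype=np.float64).ravel()
        if delta.size == 1:
            delta = np.repeat(delta, x.n_datasets)
        return PenaltyWeights(delta)
    return PenaltyWeights.default(x.n_datasets, config.lambda_dim, x.n_genes)


def _fitted_means(x: DatasetCollection, Z: LatentGeneEmbedding, coef: CellCoefficients):
    means = []
    for k in range(x.n_datasets):
        eta = np.clip(coef.alpha[k][None, :] + Z.Z @ coef.beta[k].T, None, LINK_CLIP)
        means.append(np.exp(eta))
    return means


def _guarded_dispersion_update(
    x: DatasetCollection,
    Z: LatentGeneEmbedding,
    coef: CellCoefficients,
    disp: DispersionField,
) -> DispersionField:
    """Moment update accepted per (gene, dataset) only where it improves the
    log-likelihood of that entry, keeping the M-step monotone."""
    means = _fitted_means(x, Z, coef)
    proposal = estimate_dispersion(x, means)
    theta = disp.theta.copy()
    for k in range(x.n_datasets):
        ll_old = model.nb_logpmf_arrays(x.datasets[k], means[k], theta[:, k][:, None]).sum(axis=1)
        ll_new = model.nb_logpmf_arrays(
            x.datasets[k], means[k], proposal.theta[:, k][:, None]
        ).sum(axis=1)
        take = ll_new >= ll_old
        theta[:, k] = np.where(take, proposal.theta[:, k], theta[:, k])
    return DispersionField(theta)


def fit(x: DatasetCollection, config: FitConfig) -> FitResult:
    """Fit the latent-variable NB model by Monte-Carlo EM.

    Alternates the MH E-step over latent gene coordinates with per-cell
    penalized NB regressions and guarded dispersion refreshes; stops when the
    3-iteration moving average of the penalized joint log-likelihood changes
    by less than ``em_tol`` (relative) over two consecutive iterations, or at
    ``n_em_iters``.
    """
    rng = np.random.default_rng(config.rng_seed)
    pen = _resolve_penalty(x, config)
    m, K = x.n_genes, x.n_datasets
    Z = _initial_embedding(x, config.lambda_dim, config.rng_seed)
    coef = CellCoefficients(
        alpha=[
            np.log(np.maximum(d.mean(axis=0), ALL_ZERO_CELL_PSEUDOMEAN)) for d in x.datasets
        ],
        beta=[np.zeros((d.shape[1], config.lambda_dim)) for d in x.datasets],
    )
    disp = _guarded_dispersion_update(
        x, LatentGeneEmbedding(np.zeros((m, config.lambda_dim))), coef,
        DispersionField(np.ones((m, K))),
    )

    trace: list[float] = []
    converged = False
    acc_rate = float("nan")
    ma_prev = None
    n_hits = 0
    for it in range(config.n_em_iters):
        # M-step: per-cell penalized NB regression, then guarded theta refresh
        new_alpha, new_beta = [], []
        for k in range(K):
            a, b = _update_dataset_coefficients(
                x.datasets[k],
                Z.Z,
                disp.theta[:, k],
                float(pen.delta[k]),
                coef.alpha[k],
                coef.beta[k],
                config.n_irls_iters,
                config.n_cd_passes,
            )
            new_alpha.append(a)
            new_beta.append(b)
        coef = CellCoefficients(alpha=new_alpha, beta=new_beta)
        disp = _guarded_dispersion_update(x, Z, coef, disp)

        # E-step: refresh the latent coordinates
        Z, acc_rate = sample_latents(x, coef, disp, Z, config, rng)

        pll = model.penalized_loglik(x, Z, coef, disp, pen)
        if not np.isfinite(pll):
            bad = np.argwhere(~np.isfinite(Z.Z))
            raise FloatingPointError(
                f"penalized log-likelihood diverged at EM iteration {it}"
                + (f"; first non-finite latent coordinate at gene {bad[0][0]}" if bad.size else "")
            )
        trace.append(pll)

        # convergence on a 3-iteration moving average of the (noisy) trace
        if len(trace) >= 3:
            ma = float(np.mean(trace[-3:]))
            if ma_prev is not None:
                rel = abs(ma - ma_prev) / max(abs(ma_prev), 1.0)
                n_hits = n_hits + 1 if rel < config.em_tol else 0
                if n_hits >= 2:
                    converged = True
                    break
            ma_prev = ma

    return FitResult(
        embedding=Z,
        coef=coef,
        disp=disp,
        loglik_trace=trace,
        converged=converged,
        config=config,
        mh_acceptance=acc_rate,
    )


def select_lambda_bic(
    x: DatasetCollection,
    candidate_lambdas,
    config: FitConfig,
) -> tuple[int, list[dict]]:
    """Fit each candidate latent dimension and pick the BIC minimiser.

    ``BIC = -2 * joint log-likelihood + p * log(N)`` with
    ``p = sum_k n_k (1 + lambda) + m * lambda`` free quantities (cell
    coefficients plus latent coordinates) and ``N = m * sum_k n_k``
    observations. Ties break toward the smaller lambda.
    """
    candidates = list(candidate_lambdas)
    if not candidates:
        raise ValueError("need at least one candidate lambda")
    N = x.n_genes * x.total_cells
    table: list[dict] = []
    best_lambda, best_bic = None, np.inf
    for lam in candidates:
        row = {"lambda": int(lam), "bic": np.nan, "joint_loglik": np.nan, "ok": False}
        try:
            res = fit(x, replace(config, lambda_dim=int(lam)))
            jll = model.joint_loglik(x, res.embedding, res.coef, res.disp)
            p = sum(n * (1 + lam) for n in x.n_cells) + x.n_genes * lam
            bic = -2.0 * jll + p * np.log(N)
            row.update(bic=float(bic), joint_loglik=float(jll), ok=True)
            if bic < best_bic - 1e-12:
                best_lambda, best_bic = int(lam), float(bic)
        except Exception as exc:  # noqa: BLE001 - candidate isolation
            warnings.warn(f"lambda={lam} fit failed and is excluded: {exc}", RuntimeWarning)
        table.append(row)
    if best_lambda is None:
        raise RuntimeError("every candidate lambda failed to fit")
    return best_lambda, table
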