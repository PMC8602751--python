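"""MCEM machinery: dispersion moments, penalized M-step, MH sampler, EM driver."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize
from scipy.special import gammaln

from nblatent import (
    CellCoefficients,
    DatasetCollection,
    DispersionField,
    FitConfig,
    LatentGeneEmbedding,
    PartitionPair,
    PenaltyWeights,
    adjusted_rand_index,
    cluster_latent,
    estimate_dispersion,
    fit,
    penalized_loglik,
    sample_latents,
    select_lambda_bic,
    update_cell_coefficients,
)
from conftest import model_generated_collection


class TestEstimateDispersion:
    def test_moment_inversion(self):
        """mean 2, variance 6 around a flat fit of 2 -> theta = 4/(6-2) = 1."""
        # counts 0,2,2,4 with fitted mean 2: mean 2, residual second moment 2;
        # build instead an exact case: values (0, 4) repeated -> s2 = 4, ubar = 2
        counts = np.array([[0, 4, 0, 4, 0, 4]])
        x = DatasetCollection([np.vstack([counts, counts])], ["a", "b"])
        means = [np.full((2, 6), 2.0)]
        disp = estimate_dispersion(x, means)
        # s2 = mean((x-2)^2) = 4, theta = 4/(4-2) = 2
        assert disp.theta[0, 0] == pytest.approx(2.0)

    def test_underdispersed_clamped(self):
        counts = np.array([[2, 2, 2, 2]])
        x = DatasetCollection([np.vstack([counts, counts])], ["a", "b"])
        disp = estimate_dispersion(x, [np.full((2, 4), 2.0)])
        assert disp.theta[0, 0] == 1e8

    def test_recovers_simulated_theta(self):
        rng = np.random.default_rng(1)
        u, theta, n = 5.0, 2.0, 2000
        counts = rng.negative_binomial(theta, theta / (theta + u), size=(2, n))
        x = DatasetCollection([counts], ["a", "b"])
        disp = estimate_dispersion(x, [np.full((2, n), u)])
        assert 1.5 <= disp.theta[0, 0] <= 2.7

    def test_requires_positive_means(self):
        x = DatasetCollection([np.ones((2, 2))], ["a", "b"])
        with pytest.raises(ValueError):
            estimate_dispersion(x, [np.zeros((2, 2))])


def percell_objective(xcol, Z, theta, delta):
    def obj(p):
        al, be = p[0], p[1:]
        u = np.exp(np.clip(al + Z @ be, None, 30))
        ll = (
            gammaln(xcol + theta)
            - gammaln(theta)
            - gammaln(1.0 + xcol)
            + theta * np.log(theta / (theta + u))
            + xcol * np.log(u / (theta + u))
        )
        return -ll.sum() + delta * np.abs(be).sum()

    return obj


class TestMStep:
    @pytest.mark.parametrize("delta", [0.0, 0.1, 0.5])
    def test_matches_numerical_optimizer(self, delta):
        rng = np.random.default_rng(17)
        m, lam = 5, 2
        Z = LatentGeneEmbedding(rng.normal(size=(m, lam)))
        theta = rng.uniform(1, 5, size=m)
        xcol = rng.poisson(5, size=m).astype(float)
        alpha, beta = update_cell_coefficients(xcol, Z, theta, delta)
        obj = percell_objective(xcol, Z.Z, theta, delta)
        ours = obj(np.r_[alpha, beta])
        ref = minimize(
            obj, np.zeros(lam + 1), method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 10000},
        )
        assert ours <= ref.fun + 1e-4

    def test_huge_penalty_gives_intercept_only(self):
        rng = np.random.default_rng(3)
        Z = LatentGeneEmbedding(rng.normal(size=(8, 2)))
        xcol = rng.poisson(4, size=8)
        alpha, beta = update_cell_coefficients(xcol, Z, np.full(8, 2.0), 1e9)
        np.testing.assert_array_equal(beta, 0.0)
        # intercept-only NB MLE with common theta is the log sample mean
        assert alpha == pytest.approx(np.log(xcol.mean()), abs=1e-8)

    def test_constant_column_shrunk_by_l1(self):
        """An all-ones latent column duplicates the intercept; any positive
        penalty resolves the tie by zeroing the loading."""
        rng = np.random.default_rng(4)
        Z = LatentGeneEmbedding(np.ones((10, 1)))
        xcol = rng.poisson(6, size=10)
        _, beta = update_cell_coefficients(xcol, Z, np.full(10, 3.0), 0.5)
        assert abs(beta[0]) < 1e-8

    def test_all_zero_cell_floored(self):
        Z = LatentGeneEmbedding(np.random.default_rng(0).normal(size=(4, 2)))
        with pytest.warns(RuntimeWarning, match="all-zero"):
            alpha, beta = update_cell_coefficients(np.zeros(4), Z, np.ones(4), 0.1)
        assert alpha == pytest.approx(np.log(1e-4))
        np.testing.assert_array_equal(beta, 0.0)

    def test_negative_penalty_rejected(self):
        Z = LatentGeneEmbedding(np.zeros((3, 1)))
        with pytest.raises(ValueError):
            update_cell_coefficients(np.ones(3), Z, np.ones(3), -1.0)


class TestSampleLatents:
    def _flat_setup(self, m=40, lam=2, n=5):
        """beta = 0 everywhere: the latent posterior equals the prior."""
        rng = np.random.default_rng(0)
        x = DatasetCollection([rng.poisson(3, size=(m, n))], [f"g{i}" for i in range(m)])
        coef = CellCoefficients(alpha=[np.ones(n)], beta=[np.zeros((n, lam))])
        disp = DispersionField(np.ones((m, 1)) * 2.0)
        return x, coef, disp, lam

    def test_flat_likelihood_samples_prior(self):
        x, coef, disp, lam = self._flat_setup()
        S = 5000
        cfg = FitConfig(lambda_dim=lam, n_mcmc_samples=S, mcmc_burnin=200, proposal_sd=1.2, rng_seed=5)
        Z0 = LatentGeneEmbedding(np.zeros((x.n_genes, lam)))
        Z, acc = sample_latents(x, coef, disp, Z0, cfg)
        assert 0.0 < acc < 1.0
        # posterior-mean entries across genes/dims ~ mean of N(0,1) averages
        pooled = Z.Z.ravel()
        assert abs(pooled.mean()) < 4 / np.sqrt(len(pooled) * 5)
        # chain averaging shrinks variance far below 1; just demand symmetry
        # and run a single long-chain marginal check instead:
        samples = []
        rng = np.random.default_rng(7)
        # direct check: one gene, collect raw draws via repeated single-sample calls
        # (covered more sharply by the quadrature test below)

    def test_seeded_determinism(self):
        x, coef, disp, lam = self._flat_setup(m=10)
        cfg = FitConfig(lambda_dim=lam, n_mcmc_samples=50, mcmc_burnin=20, rng_seed=9)
        Z0 = LatentGeneEmbedding(np.zeros((10, lam)))
        a, _ = sample_latents(x, coef, disp, Z0, cfg)
        b, _ = sample_latents(x, coef, disp, Z0, cfg)
        assert np.array_equal(a.Z, b.Z)

    def test_posterior_mean_matches_quadrature(self):
        """1 gene, 1 cell, lambda=1: MH mean vs numerical integration."""
        alpha, beta, theta, count = 0.5, 0.8, 2.0, 7
        x = DatasetCollection([np.array([[count], [0]])], ["g0", "g1"])
        coef = CellCoefficients(alpha=[np.array([alpha])], beta=[np.array([[beta]])])
        disp = DispersionField(np.array([[theta], [theta]]))

        def unnorm(z):
            u = np.exp(alpha + beta * z)
            lik = np.exp(
                gammaln(count + theta) - gammaln(theta) - gammaln(1 + count)
                + theta * np.log(theta / (theta + u)) + count * np.log(u / (theta + u))
            )
            return lik * np.exp(-0.5 * z**2)

        norm = quad(unnorm, -10, 10)[0]
        target_mean = quad(lambda z: z * unnorm(z), -10, 10)[0] / norm
        target_var = quad(lambda z: z**2 * unnorm(z), -10, 10)[0] / norm - target_mean**2

        S = 4000
        cfg = FitConfig(lambda_dim=1, n_mcmc_samples=S, mcmc_burnin=500, proposal_sd=0.8, rng_seed=13)
        Z0 = LatentGeneEmbedding(np.zeros((2, 1)))
        Z, _ = sample_latents(x, coef, disp, Z0, cfg)
        # generous ESS discount for random-walk autocorrelation
        mc_se = np.sqrt(target_var / (S / 20))
        assert abs(Z.Z[0, 0] - target_mean) < 3 * mc_se


class TestFit:
    def test_recovers_model_generated_clusters(self):
        coll, labels, _ = model_generated_collection(seed=42)
        cfg = FitConfig(lambda_dim=3, n_mcmc_samples=80, mcmc_burnin=40, n_em_iters=8, rng_seed=7)
        res = fit(coll, cfg)
        assign = cluster_latent(res.embedding, 3, seed=0)
        assert adjusted_rand_index(PartitionPair(labels, assign.labels)) >= 0.9

    def test_single_dataset_runs(self):
        coll, labels, _ = model_generated_collection(seed=1, K=1, n=80)
        cfg = FitConfig(lambda_dim=3, n_mcmc_samples=40, mcmc_burnin=20, n_em_iters=3, rng_seed=1)
        res = fit(coll, cfg)
        assert res.embedding.Z.shape == (60, 3)
        assert np.all(np.isfinite(res.loglik_trace))

    def test_seeded_determinism(self):
        coll, _, _ = model_generated_collection(seed=5, m=30, n=40)
        cfg = FitConfig(lambda_dim=3, n_mcmc_samples=30, mcmc_burnin=15, n_em_iters=3, rng_seed=2)
        a = fit(coll, cfg)
        b = fit(coll, cfg)
        assert np.array_equal(a.embedding.Z, b.embedding.Z)
        assert a.loglik_trace == b.loglik_trace

    def test_mstep_monotone_in_penalized_loglik(self):
        """With Z held fixed, a full M-step never lowers the penalized objective."""
        from nblatent.inference import (
            _guarded_dispersion_update,
            _resolve_penalty,
            _update_dataset_coefficients,
        )

        coll, _, _ = model_generated_collection(seed=9, m=30, n=40)
        cfg = FitConfig(lambda_dim=3, n_mcmc_samples=30, mcmc_burnin=15, n_em_iters=2, rng_seed=3)
        res = fit(coll, cfg)
        Z, coef, disp = res.embedding, res.coef, res.disp
        pen = _resolve_penalty(coll, cfg)
        before = penalized_loglik(coll, Z, coef, disp, pen)
        new_alpha, new_beta = [], []
        for k in range(coll.n_datasets):
            a, b = _update_dataset_coefficients(
                coll.datasets[k], Z.Z, disp.theta[:, k], float(pen.delta[k]),
                coef.alpha[k], coef.beta[k], 4, 8,
            )
            new_alpha.append(a)
            new_beta.append(b)
        coef2 = CellCoefficients(new_alpha, new_beta)
        disp2 = _guarded_dispersion_update(coll, Z, coef2, disp)
        after = penalized_loglik(coll, Z, coef2, disp2, pen)
        assert after >= before - 1e-8

    def test_batch_permutation_invariance(self):
        """Reordering datasets permutes coefficients and leaves Z identical."""
        coll, _, _ = model_generated_collection(seed=11, m=24, n=30, K=2)
        flipped = DatasetCollection(
            datasets=coll.datasets[::-1],
            gene_ids=coll.gene_ids,
            dataset_ids=list(coll.dataset_ids)[::-1],
        )
        cfg = FitConfig(lambda_dim=3, n_mcmc_samples=30, mcmc_burnin=15, n_em_iters=3, rng_seed=4)
        a = fit(coll, cfg)
        b = fit(flipped, cfg)
        assert np.array_equal(a.embedding.Z, b.embedding.Z)
        assert np.array_equal(a.coef.alpha[0], b.coef.alpha[1])
        assert np.array_equal(a.coef.beta[1], b.coef.beta[0])

    def test_converged_fit_is_stable(self):
        """Doubling the iteration budget from a converged state barely moves
        the penalized log-likelihood."""
        coll, _, _ = model_generated_collection(seed=21, m=30, n=50)
        cfg = FitConfig(lambda_dim=3, n_mcmc_samples=60, mcmc_burnin=30, n_em_iters=12,
                        em_tol=1e-3, rng_seed=5)
        short = fit(coll, cfg)
        from dataclasses import replace

        long = fit(coll, replace(cfg, n_em_iters=24))
        rel = abs(long.loglik_trace[-1] - short.loglik_trace[-1]) / abs(short.loglik_trace[-1])
        assert rel < 10 * cfg.em_tol


class TestBICSelection:
    def test_single_candidate(self):
        coll, _, _ = model_generated_collection(seed=2, m=24, n=30)
        cfg = FitConfig(n_mcmc_samples=30, mcmc_burnin=15, n_em_iters=2, rng_seed=1)
        best, table = select_lambda_bic(coll, [3], cfg)
        assert best == 3
        assert len(table) == 1 and np.isfinite(table[0]["bic"])

    def test_table_structure(self):
        coll, _, _ = model_generated_collection(seed=2, m=24, n=30)
        cfg = FitConfig(n_mcmc_samples=30, mcmc_burnin=15, n_em_iters=2, rng_seed=1)
        best, table = select_lambda_bic(coll, [2, 3], cfg)
        assert [row["lambda"] for row in table] == [2, 3]
        assert all(np.isfinite(row["bic"]) for row in table)
        assert best in (2, 3)
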