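"""Choose the latent dimension by BIC.

Fits a range of latent dimensions to one simulated collection and prints the
BIC table. Lower BIC is preferred; note that for cluster-counting purposes
BIC is conservative here — c cluster centroids always embed in c-1 latent
dimensions, so the likelihood gain of the c-th dimension is modest and BIC
often prefers the smaller space. The latent dimension can always be set by
preference instead.
"""

from nblatent import FitConfig, generate_nb_cohort, select_lambda_bic

cohort = generate_nb_cohort(n_sets=2, cells_per_dataset=80, seed=3)
x = cohort.collections[1]

config = FitConfig(n_mcmc_samples=60, mcmc_burnin=30, n_em_iters=5, rng_seed=3)
best, table = select_lambda_bic(x, [2, 3, 4], config)

print("lambda   BIC           joint log-lik")
for row in table:
    print(f"{row['lambda']:<8d}{row['bic']:<14.1f}{row['joint_loglik']:.1f}")
print(f"selected lambda = {best} (minimum BIC, ties toward smaller)")
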