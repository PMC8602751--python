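import numpy as np
import pytest

from nblatent import (
    CellCoefficients,
    DatasetCollection,
    DispersionField,
    LatentGeneEmbedding,
)


@pytest.fixture
def tiny_collection() -> DatasetCollection:
    """2 genes x 2 cells x 2 datasets with hand-picked counts."""
    return DatasetCollection(
        datasets=[np.array([[0, 3], [5, 1]]), np.array([[2, 2], [0, 7]])],
        gene_ids=["gA", "gB"],
        dataset_ids=["d1", "d2"],
    )


@pytest.fixture
def tiny_params(tiny_collection):
    rng = np.random.default_rng(11)
    lam = 2
    Z = LatentGeneEmbedding(rng.normal(size=(2, lam)))
    coef = CellCoefficients(
        alpha=[rng.normal(0.5, 0.2, size=2) for _ in range(2)],
        beta=[rng.normal(0.0, 0.4, size=(2, lam)) for _ in range(2)],
    )
    disp = DispersionField(rng.uniform(0.5, 4.0, size=(2, 2)))
    return Z, coef, disp


def model_generated_collection(seed=42, m=60, lam=3, K=2, n=100, theta=2.0, sep=2.0):
    """Counts drawn from the latent NB model itself, with 3 latent clusters.

    Returns (collection, true labels, true Z).
    """
    rng = np.random.default_rng(seed)
    centers = sep * np.eye(lam)[:3] if lam >= 3 else sep * np.eye(lam)
    labels = np.repeat(np.arange(1, 4), m // 3)
    Z_true = centers[labels - 1] + 0.3 * rng.normal(size=(m, lam))
    datasets = []
    for _ in range(K):
        alpha = rng.normal(1.0, 0.3, size=n)
        beta = rng.normal(0.5, 0.3, size=(n, lam))
        eta = np.clip(alpha[None, :] + Z_true @ beta.T, None, 30)
        u = np.exp(eta)
        datasets.append(rng.negative_binomial(theta, theta / (theta + u)))
    coll = DatasetCollection(datasets, [f"g{i}" for i in range(m)])
    return coll, labels, Z_true
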