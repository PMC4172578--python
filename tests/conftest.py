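import numpy as np
import pytest

from supergwas import (
    GenotypeMatrix,
    ModelSpec,
    PopulationModel,
    VariantInfo,
    compute_kinship,
    simulate_genotypes,
    simulate_phenotype,
)


def make_matrix(dosages, chrom=None, positions=None, samples=None):
    """Build a GenotypeMatrix from a plain array with simple metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    chrom = chrom or ["1"] * m
    positions = positions or list(range(100, 100 * (m + 1), 100))
    samples = samples or [f"s{i}" for i in range(n)]
    variants = [
        VariantInfo(id=f"m{j + 1}", chromosome=chrom[j], position=positions[j])
        for j in range(m)
    ]
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


@pytest.fixture
def tiny_matrix():
    """3 samples x 2 markers, the hand-checkable kinship example."""
    return make_matrix([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]],
                       samples=["A", "B", "C"])


@pytest.fixture(scope="session")
def small_panel():
    """A modest structured panel shared across tests (100 x 500)."""
    model = PopulationModel(
        chromosomes=[(str(c + 1), 100, 50_000_000) for c in range(5)]
    )
    return simulate_genotypes(model, n_per_subpop=50, seed=11)


@pytest.fixture(scope="session")
def small_trait(small_panel):
    return simulate_phenotype(small_panel, n_qtn=10, h2=0.75, seed=23)


@pytest.fixture(scope="session")
def small_spec(small_panel):
    return ModelSpec.from_covariates(small_panel.n_samples)


@pytest.fixture(scope="session")
def small_kinship(small_panel):
    return compute_kinship(small_panel, keep_crossproduct=True)


def random_instance(rng, n=12, m=30, h2=0.5, q=1):
    """Small random mixed-model instance for oracle comparisons."""
    dosages = rng.integers(0, 3, size=(n, m)).astype(float)
    G = make_matrix(dosages)
    K = compute_kinship(G)
    X = np.ones((n, q))
    if q > 1:
        X = np.column_stack([np.ones(n), rng.normal(size=(n, q - 1))])
    L = np.linalg.cholesky(K.values + 1e-6 * np.eye(n))
    g = L @ rng.normal(size=n)
    va = g.var()
    ve = va * (1 - h2) / h2 if va > 0 else 1.0
    y = g + rng.normal(0, np.sqrt(ve), size=n)
    return y, ModelSpec(X=X), K, G
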