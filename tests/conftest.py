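import numpy as np
import pytest

from zinbmix import (
    CountMatrix,
    ModelParams,
    simulate_counts,
    two_gene_benchmark_spec,
)
from zinbmix.model_core import unit_scalers


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_params(K=2, L=2, G=2, seed=0, q0=0.2):
    """Random valid parameters for toy instances."""
    rng = np.random.default_rng(seed)
    pi = rng.dirichlet(np.ones(K) * 5)
    n_nb = L - 1 if L >= 2 else 1
    alpha = rng.uniform(0.5, 20.0, size=(G, K, n_nb))
    beta = rng.uniform(0.3, 3.0, size=(G, K, n_nb))
    q = np.empty((G, K, L))
    if L >= 2:
        q[..., 0] = q0
        rest = rng.dirichlet(np.ones(n_nb), size=(G, K))
        q[..., 1:] = (1 - q0) * rest
    else:
        q[..., 0] = 1.0
    return ModelParams(K, L, pi, q, alpha, beta).validate()


@pytest.fixture
def toy_params():
    return make_params(K=2, L=2, G=2, seed=7)


@pytest.fixture
def toy_counts():
    return CountMatrix(np.array([[0, 3], [5, 0], [2, 2]]))


@pytest.fixture(scope="session")
def two_gene_dataset():
    """A 4000-cell draw of the two-gene benchmark, shared across tests."""
    ds = simulate_counts(two_gene_benchmark_spec(n_cells=4000, seed=11))
    return ds


@pytest.fixture
def unit_s():
    def _make(n):
        return unit_scalers(n)

    return _make
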