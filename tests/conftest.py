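import numpy as np
import pandas as pd
import pytest

from velostab.containers import CountMatrix
from velostab.synthdata import make_dataset


def nb_counts(rng, mu, gamma, size):
    """Direct NB(mu, gamma) sampler used as test input generator."""
    if np.isinf(gamma):
        return rng.poisson(mu, size=size)
    return rng.negative_binomial(gamma, gamma / (gamma + mu), size=size)


def count_matrix(X, layer="counts"):
    X = np.atleast_2d(X)
    n, p = X.shape
    return CountMatrix(
        X,
        gene_ids=pd.Index([f"g{j}" for j in range(p)]),
        cell_ids=pd.Index([f"c{i}" for i in range(n)]),
        layer_name=layer,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale kinetic dataset shared across tests (150 cells)."""
    return make_dataset(150, 20, 40, master_seed=7)


@pytest.fixture(scope="session")
def default_dataset():
    """The default-sized dataset (500 cells, 100 kinetic + 200 noise genes)."""
    return make_dataset(500, 100, 200, master_seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
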