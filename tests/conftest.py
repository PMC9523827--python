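import numpy as np
import pytest

import gsrank as g


@pytest.fixture(scope="session")
def ordinal_model():
    """The 5-category latent-Beta alternative with true p = 0.6."""
    return g.latent_beta_ordinal_model(0.6974797, 1, 3, 3)


@pytest.fixture(scope="session")
def null_normal_model():
    return g.normal_model(0, 1, 0, 1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)


def brute_force_relative_effect(x1, x2):
    """Independent pairwise-count oracle for p_hat."""
    x1 = np.asarray(x1, float)[:, None]
    x2 = np.asarray(x2, float)[None, :]
    c = np.where(x2 > x1, 1.0, np.where(x2 == x1, 0.5, 0.0))
    return c.mean()


def brute_force_midranks(values):
    """Direct c-kernel sum definition of midranks."""
    v = np.asarray(values, float)
    c = np.where(v[:, None] > v[None, :], 1.0, np.where(v[:, None] == v[None, :], 0.5, 0.0))
    return 0.5 + c.sum(axis=1)


def random_tied_dataset(rng, max_n=30, n_levels=6):
    n1 = int(rng.integers(2, max_n))
    n2 = int(rng.integers(2, max_n))
    x1 = rng.integers(1, n_levels + 1, n1).astype(float)
    x2 = rng.integers(1, n_levels + 1, n2).astype(float)
    return x1, x2
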