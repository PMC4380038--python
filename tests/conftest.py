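import numpy as np
import pytest

from ensdist import TriadTree, gtr_rate_matrix, make_rate_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(20140901)


@pytest.fixture(scope="session")
def tree():
    return TriadTree(("a", "b"), "c")


def random_rate_matrix(rng, low=0.05, high=1.0):
    """A generic irreducible generator (not reversible in general)."""
    return make_rate_matrix(rng.uniform(low, high, size=12))


def random_reversible_matrix(rng):
    """A random GTR generator: symmetric exchangeabilities times frequencies."""
    pi = np.clip(rng.dirichlet(np.full(4, 5.0)), 0.05, None)
    pi = pi / pi.sum()
    return gtr_rate_matrix(rng.uniform(0.3, 2.0, size=6), pi)


def random_distribution(rng, concentration=2.0):
    p = rng.dirichlet(np.full(4, concentration))
    p = np.clip(p, 1e-6, None)
    return p / p.sum()
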