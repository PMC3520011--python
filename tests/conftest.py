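import numpy as np
import pytest

import connfield as cf


@pytest.fixture(scope="session")
def footprint66():
    """Truncated exponential footprint at the tractography-matrix scale."""
    return cf.make_exponential_footprint(66, cf.KernelSpec(sigma=5.0))


@pytest.fixture(scope="session")
def circulant64():
    """Circulant footprint whose eigenmodes are exact sinusoids."""
    return cf.make_exponential_footprint(
        64, cf.KernelSpec(sigma=5.0, boundary="circulant")
    )


@pytest.fixture(scope="session")
def planted_two_block():
    """Two 10-node communities, strong within / weak between weights."""
    return cf.make_planted_modular([10, 10], w_in=1.0, w_out=0.05)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_symmetric(n: int, seed: int, density: float = 0.6) -> cf.ConnectivityMatrix:
    """Seeded random weighted undirected graph (no self-loops)."""
    r = np.random.default_rng(seed)
    w = np.triu(r.random((n, n)) * (r.random((n, n)) < density), 1)
    w = w + w.T
    if w.sum() == 0:  # ensure at least one edge
        w[0, 1] = w[1, 0] = 1.0
    return cf.ConnectivityMatrix(weights=w)
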