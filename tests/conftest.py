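import numpy as np
import pytest

from netinfospec import LinearNetwork, make_scale_free


@pytest.fixture(scope="session")
def ba20() -> LinearNetwork:
    """Small scale-free network: 20 nodes, 5 drivers."""
    return make_scale_free(20, 5, seed=3)


@pytest.fixture(scope="session")
def ba10_full() -> LinearNetwork:
    """Fully actuated 10-node scale-free network."""
    return make_scale_free(10, 10, seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_stable_network(n: int, seed: int, m: int | None = None) -> LinearNetwork:
    """A generic (non-graph) stable test system: symmetric negative-definite
    A, dense full-rank B, identity noise."""
    r = np.random.default_rng(seed)
    M = r.standard_normal((n, n))
    A = -(M @ M.T) / n - 0.5 * np.eye(n)
    m = n if m is None else m
    B = r.standard_normal((n, m))
    return LinearNetwork(A=A, B=B, Sigma_w=np.eye(n), n_d=m)
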