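import numpy as np
import pytest

from dghd import Network, er_network, rg_network


@pytest.fixture
def path3() -> Network:
    """3-node path 1-2-3."""
    return Network.from_edges([("1", "2"), ("2", "3")], nodes=["1", "2", "3"])


@pytest.fixture
def star4() -> Network:
    """Star on 4 nodes with centre c."""
    return Network.from_edges([("c", "x"), ("c", "y"), ("c", "z")],
                              nodes=["c", "x", "y", "z"])


@pytest.fixture
def k4() -> Network:
    a = np.ones((4, 4), dtype=np.int8)
    np.fill_diagonal(a, 0)
    return Network(("1", "2", "3", "4"), a)


@pytest.fixture
def empty5() -> Network:
    return Network(tuple("abcde"), np.zeros((5, 5), dtype=np.int8))


def random_pair(n: int, p: float, seed: int):
    rng = np.random.default_rng(seed)
    return er_network(n, p=p, seed=rng), er_network(n, p=p, seed=rng)


@pytest.fixture
def rg_pair_250():
    rng = np.random.default_rng(42)
    return rg_network(250, 0.3, seed=rng), rg_network(250, 0.3, seed=rng)
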