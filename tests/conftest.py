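import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from rootmorph.network import CellNetwork, MechParams, initial_network

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def mech() -> MechParams:
    return MechParams()


@pytest.fixture
def net20(mech) -> CellNetwork:
    """A relaxed 20-cell tissue (function-scoped: tests may mutate it)."""
    return initial_network(20, seed=7, mech=mech)


@pytest.fixture
def hexagon(mech) -> CellNetwork:
    return initial_network(1, seed=0, mech=mech)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def square_pair() -> CellNetwork:
    """Two unit squares sharing one wall — the smallest hand-checkable
    multi-cell network."""
    net = CellNetwork()
    v = {}
    for i, (x, y) in enumerate([(0, 0), (1, 0), (2, 0),
                                (2, 1), (1, 1), (0, 1)]):
        v[i] = net.add_vertex(float(x), float(y))
    net.add_cell([v[0], v[1], v[4], v[5]])
    net.add_cell([v[1], v[2], v[3], v[4]])
    net.validate()
    return net
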