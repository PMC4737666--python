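import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from conngeo.io import NodeTable, WeightedConnectome
from conngeo.synthetic import DEFAULT_SPEC, make_modular_connectome

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def chain_connectome():
    """A-B=1, B-C=4: the minimal weighted chain used in worked examples."""
    w = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 4.0], [0.0, 4.0, 0.0]])
    return WeightedConnectome(w, ("A", "B", "C"))


@pytest.fixture
def star_connectome():
    """Hub node H plus 3 leaves with unit weights."""
    w = np.zeros((4, 4))
    w[0, 1:] = w[1:, 0] = 1.0
    return WeightedConnectome(w, ("H", "L1", "L2", "L3"))


@pytest.fixture
def unit_square():
    return np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])


def random_connected_connectome(rng: np.random.Generator, n: int) -> WeightedConnectome:
    """Random symmetric weighted graph, guaranteed connected via a ring backbone."""
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(iu.size) < 0.35
    vals = rng.lognormal(0.0, 0.8, iu.size) * present
    w[iu, ju] = w[ju, iu] = vals
    for i in range(n):  # ring keeps every node attached and the graph connected
        j = (i + 1) % n
        if w[i, j] == 0:
            w[i, j] = w[j, i] = rng.lognormal(0.0, 0.5)
    return WeightedConnectome(w)


@pytest.fixture
def connectome_factory():
    return random_connected_connectome


@pytest.fixture(scope="session")
def default_synthetic():
    """Default planted-core connectome (seed 1), shared across tests."""
    from dataclasses import replace

    return make_modular_connectome(replace(DEFAULT_SPEC, seed=1))
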