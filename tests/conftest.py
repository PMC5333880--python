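import pytest

from angiopn.core_net import PetriNet
from angiopn.synthetic_data import generate_covered_net, load_angiogenesis_fixture


@pytest.fixture(scope="session")
def angiogenesis():
    """(support matrix 48x74, MCT sets m1..m11, expected knockout table)."""
    return load_angiogenesis_fixture()


@pytest.fixture
def chain_net():
    """p1 -> t1 -> p2 with one token on p1."""
    return PetriNet(
        ["p1", "p2"], ["t1"], [("p1", "t1", 1), ("t1", "p2", 1)], {"p1": 1}
    )


@pytest.fixture
def cycle_net():
    """Closed two-transition loop p1 -> t1 -> p2 -> t2 -> p1."""
    return PetriNet(
        ["p1", "p2"],
        ["t1", "t2"],
        [("p1", "t1", 1), ("t1", "p2", 1), ("p2", "t2", 1), ("t2", "p1", 1)],
        {"p1": 1},
    )


@pytest.fixture(params=range(8))
def random_net(request):
    """A batch of seeded circuit-union nets of varying shape."""
    shapes = [(4, 6, 2), (5, 8, 3), (6, 8, 3), (7, 10, 4)]
    n_p, n_t, n_c = shapes[request.param % len(shapes)]
    return generate_covered_net(n_p, n_t, n_c, seed=request.param)
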