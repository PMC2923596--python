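import numpy as np
import pytest

import ppinet as pp


@pytest.fixture(scope="session")
def er_net():
    """Mid-sized Erdős–Rényi graph shared across statistical tests."""
    return pp.erdos_renyi(2000, 5, seed=1)


@pytest.fixture(scope="session")
def er_null_ensemble(er_net):
    """Ten equilibrated randomisations (>= 100 accepted moves per link)."""
    return [
        pp.randomise(er_net, pp.RandomisationConfig(seed=1000 + s))
        for s in range(10)
    ]


@pytest.fixture()
def small_graphs():
    """A bundle of exactly constructed toy graphs."""
    return {
        "star": pp.star(3),
        "cycle4": pp.cycle(4),
        "path5": pp.path(5),
        "matching": pp.perfect_matching(3),
    }


def assert_valid_network(net: pp.InteractionNetwork) -> None:
    assert net.N >= 1
    assert 0 <= net.E <= net.N * (net.N - 1) // 2
    for i, j in net.edges:
        assert i != j
        assert 0 <= i < j < net.N
    deg = net.degree_sequence()
    assert int(deg.sum()) == 2 * net.E
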