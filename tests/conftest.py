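import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import misinfogame as mg

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def lattice30():
    return mg.make_lattice(30, 30)


@pytest.fixture(scope="session")
def two_viable():
    """Path C-X-Y-C: two adjacent viable nodes, one A and one B.

    Every asynchronous update flips the drawn viable node to the other's
    strategy (its single non-sanctioner neighbor), so the first viable
    draw decides the outcome and P(A fixates) is exactly 1/2 for any
    payoff matrix.
    """
    graph = mg.Graph.from_edges(4, [(0, 1), (1, 2), (2, 3)])
    strategies = np.array([2, 0, 1, 2], dtype=np.int8)
    mask = np.array([True, False, False, True])
    return graph, mg.PopulationState(strategies, mask)


@pytest.fixture(scope="session")
def corner_sanctioned():
    """3x3 open lattice with sanctioners in the corners, 5 viable nodes.

    Viable cross: nodes 1, 3, 4, 5, 7; nodes 1 and 3 start as A.
    """
    graph = mg.make_lattice(3, 3, periodic=False)
    strategies = np.full(9, 1, dtype=np.int8)
    mask = np.zeros(9, dtype=bool)
    for i in (0, 2, 6, 8):
        mask[i] = True
        strategies[i] = 2
    strategies[1] = 0
    strategies[3] = 0
    return graph, mg.PopulationState(strategies, mask)
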