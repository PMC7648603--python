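import numpy as np
import pytest

from rugard.rd_core import SignedTopology
from rugard.topology_space import (
    enumerate_minimal_topologies,
    filter_funnel_3node,
    RUGA3_LABELS,
    RUGA3_PHASES,
    RUGA5_LABELS,
    RUGA5_PHASES,
)


@pytest.fixture(scope="session")
def ai_topology():
    """Classic activator-inhibitor pair: U autoactivates, activates V; V inhibits U."""
    return SignedTopology(sign=((1, -1), (1, 0)), autoreg=(True, False), labels=("U", "V"))


@pytest.fixture(scope="session")
def sd_topology():
    """Substrate depletion: S fuels the autoactivating A, which consumes S."""
    return SignedTopology(sign=((1, 1), (-1, 0)), autoreg=(True, False), labels=("A", "S"))


@pytest.fixture(scope="session")
def minset3():
    return enumerate_minimal_topologies(RUGA3_LABELS, RUGA3_PHASES)


@pytest.fixture(scope="session")
def funnel3():
    return filter_funnel_3node()


@pytest.fixture(scope="session")
def minset5():
    return enumerate_minimal_topologies(RUGA5_LABELS, RUGA5_PHASES)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
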