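import numpy as np
import pytest

from hemigait.model_core import LesionSpec, apply_lesion, build_network
from hemigait.sim_engine import speed_sweep

ACCEPT_DURATION = 25.0
ACCEPT_TRANSIENT = 9.0
TIED_GRID = np.round(np.arange(0.4, 1.01, 0.1), 10)
FAST_GRID = np.round(np.arange(0.5, 1.01, 0.1), 10)


@pytest.fixture(scope="session")
def intact_network():
    return build_network()


@pytest.fixture(scope="session")
def hemisected_network(intact_network):
    return apply_lesion(intact_network, LesionSpec("right_hemisected"))


@pytest.fixture(scope="session")
def transected_network(intact_network):
    return apply_lesion(intact_network, LesionSpec("transected"))


@pytest.fixture(scope="session")
def tied_sweeps(intact_network, hemisected_network):
    """Intact and right-hemisected tied-belt sweeps over the protocol grid."""
    swi = speed_sweep(intact_network, "tied", TIED_GRID, duration=ACCEPT_DURATION, transient=ACCEPT_TRANSIENT)
    swh = speed_sweep(hemisected_network, "tied", TIED_GRID, duration=ACCEPT_DURATION, transient=ACCEPT_TRANSIENT)
    return swi, swh


@pytest.fixture(scope="session")
def split_lsrf_sweep(hemisected_network):
    return speed_sweep(hemisected_network, "split_Ls_Rf", FAST_GRID, duration=ACCEPT_DURATION, transient=ACCEPT_TRANSIENT)


@pytest.fixture(scope="session")
def split_lfrs_sweeps(intact_network, hemisected_network):
    swi = speed_sweep(intact_network, "split_Lf_Rs", FAST_GRID, duration=ACCEPT_DURATION, transient=ACCEPT_TRANSIENT)
    swh = speed_sweep(hemisected_network, "split_Lf_Rs", FAST_GRID, duration=ACCEPT_DURATION, transient=ACCEPT_TRANSIENT)
    return swi, swh


@pytest.fixture()
def rng():
    return np.random.default_rng(20240131)
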