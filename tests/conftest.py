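import numpy as np
import pytest

from holomea.layout import MEALayout
from holomea.network import generate_network
from holomea.simulate import SimConfig


@pytest.fixture(scope="session")
def layout60():
    return MEALayout.default_60mea()


@pytest.fixture(scope="session")
def small_layout():
    """3x3 grid at 100 um pitch: every neuron is near some electrode."""
    return MEALayout(3, 3, 100.0, 30.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def quiet_cfg():
    """Short recording with spontaneous firing only."""
    return SimConfig(duration_s=10.0, spont_rate_hz=1.0, burst_rate_hz=0.0)


@pytest.fixture(scope="session")
def small_net(small_layout):
    return generate_network(6, small_layout, density=0.1, seed=11)
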