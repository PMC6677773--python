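import numpy as np
import pytest

from flockhunt import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """A modest arena that runs in well under a second."""
    return SimulationConfig.from_groups(n=60, chi=604.0, aleph=0.5, kappa=5.0,
                                        tau_end=2.0, seed=7)


@pytest.fixture
def predation_cfg():
    """Low-coordination arena tuned so the predator actually kills."""
    return SimulationConfig.from_groups(n=80, chi=121.0, aleph=0.25, kappa=5.0,
                                        tau_end=12.0, seed=3, t_h=1.0)
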