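import numpy as np
import pytest

from mitoclock.core_model import RateParams, simulate_deterministic
from mitoclock.stochastic import VolumeSpec


@pytest.fixture(scope="session")
def default_params():
    return RateParams()


@pytest.fixture(scope="session")
def omega50():
    return VolumeSpec.from_omega(50.0)


@pytest.fixture(scope="session")
def osc_trajectory():
    """Long deterministic run in the oscillatory regime (r = 0.8)."""
    return simulate_deterministic(RateParams(r=0.8), (0.0, 0.0), t_end=3000.0, dt_out=1.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
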