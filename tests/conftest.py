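import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vhisim as v

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def params():
    return v.ModelParams()


@pytest.fixture
def quiet_trial():
    """Short noise-free trial config for fast deterministic integrations."""
    return v.TrialConfig(offset=15.0, duration=5.0, noise=False)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
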