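import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from patchtension.synthetic_experiment import (
    ChannelModel,
    GeometryModel,
    make_pressure_protocol,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def geometry():
    return GeometryModel()


@pytest.fixture
def traak():
    return ChannelModel()


@pytest.fixture
def noise_free_traak():
    """Idealized channel: no current noise, no resting tension."""
    return ChannelModel(basal_tension_mn_per_m=0.0, current_noise_sd_pa=0.0)


@pytest.fixture
def short_protocol():
    """Compact six-step protocol for fast pipeline tests."""
    return make_pressure_protocol(
        (-10, -20, -35, -50, -75, -110), step_duration=0.3, inter_step=0.2
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
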