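import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def gaussian_pulse(n, fs_hz, center_s, amp_uv, width_ms):
    """Render one bell-shaped test pulse on an n-sample grid."""
    t = np.arange(n) / fs_hz
    sigma_t = width_ms * 1e-3 / 6.0
    return amp_uv * np.exp(-0.5 * ((t - center_s) / sigma_t) ** 2)


@pytest.fixture
def pulse():
    return gaussian_pulse
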