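import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from aerotrack.core import CameraModel, LaserModel

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def camera():
    """Small camera with the instrument's photometric parameters."""
    return CameraModel(n_pixels_x=256, n_pixels_y=256)


@pytest.fixture
def quiet_camera():
    """Small camera with background and dark noise switched off."""
    return CameraModel(n_pixels_x=256, n_pixels_y=256,
                       background_rate=1e-12, dark_noise_sigma=1e-12)


@pytest.fixture
def full_camera():
    """Full-size instrument camera (2048x2048)."""
    return CameraModel()


@pytest.fixture
def laser():
    return LaserModel()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
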