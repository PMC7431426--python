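import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from qrap5d import fixtures as fx
from qrap5d.mask import generate_rap
from qrap5d.optics import OpticalConfig, simulate_psf

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg_fast():
    """Small, quick geometry: 64² sensor at 16 µm, u = v = 10 cm."""
    return OpticalConfig(u=0.10, v=0.10, wavelength=530e-9,
                         sensor_shape=(64, 64), pixel_pitch=16e-6)


@pytest.fixture(scope="session")
def mask_fast():
    """30 pinholes of 80 µm in 1 mm — fringe periods stay above 2 px at 16 µm."""
    return generate_rap(30, (1e-3, 1e-3), 80e-6, seed=3)


@pytest.fixture(scope="session")
def psf_fast(cfg_fast, mask_fast):
    return simulate_psf(cfg_fast, mask_fast)


@pytest.fixture(scope="session")
def cfg_full():
    return fx.default_config()


@pytest.fixture(scope="session")
def mask_full():
    return fx.default_mask()


@pytest.fixture(scope="session")
def psf_full(cfg_full, mask_full):
    return simulate_psf(cfg_full, mask_full)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
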