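"""Shared fixtures: small ground-truth scenes and curves."""
import numpy as np
import pytest

from embryotfm import GelProperties, make_contractile_traction, make_scene


@pytest.fixture
def gel():
    return GelProperties(youngs_modulus=1000.0, poisson_ratio=0.5)


@pytest.fixture
def annulus_traction():
    return make_contractile_traction()


@pytest.fixture
def clean_scene():
    """Default scene without counting noise or stage drift."""
    return make_scene(seed=11, drift_sd_px=0.0, counting_noise=False)


@pytest.fixture
def noisy_scene():
    """Default scene with counting noise and drift (study conditions)."""
    return make_scene(seed=11)


@pytest.fixture
def disk_mask():
    """Rasterized disk of radius 100 px in a 256x256 frame."""
    yy, xx = np.mgrid[0:256, 0:256]
    return (xx - 128.0) ** 2 + (yy - 128.0) ** 2 <= 100.0 ** 2
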