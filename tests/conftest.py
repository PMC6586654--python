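import numpy as np
import pytest
from scipy import ndimage

from ipet import synthetic as syn
from ipet.io import TiltSeries


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def sphere_volume():
    """Soft-edged sphere of radius 8 px centred in a 64^3 box."""
    n = 64
    g = np.arange(n) - n / 2
    r = np.sqrt(g[:, None, None] ** 2 + g[None, :, None] ** 2
                + g[None, None, :] ** 2)
    return ndimage.gaussian_filter((r < 8).astype(float), 1.0)


@pytest.fixture(scope="session")
def smooth_random_volume():
    """Random smooth density supported inside the inscribed sphere (64^3)."""
    n = 64
    v = ndimage.gaussian_filter(np.random.default_rng(0).random((n, n, n)), 3)
    g = np.arange(n) - n / 2
    r = np.sqrt(g[:, None, None] ** 2 + g[None, :, None] ** 2
                + g[None, None, :] ** 2)
    return v * (r < n / 2 - 6)


@pytest.fixture(scope="session")
def x_phantom_small():
    """Default X-shaped phantom on a 64^3 grid at 5.92 A/px."""
    spec = syn.build_phantom_spec("X")
    vol = syn.rasterize_phantom(spec, 64, 5.92)
    return spec, vol


@pytest.fixture(scope="session")
def sphere_series(sphere_volume):
    """Noise-free +/-45 deg tilt series of the sphere fixture."""
    from ipet._projector import project

    angles = np.arange(-45.0, 45.01, 1.5)
    imgs = np.stack([project(sphere_volume, a) for a in angles])
    return TiltSeries(imgs, angles, 2.96)
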