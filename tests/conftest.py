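import numpy as np
import pytest

from flara import TiltGeometry, TiltSeries, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def geom16():
    """16^3 volume, 5 tilt angles."""
    return TiltGeometry([-60.0, -30.0, 0.0, 30.0, 60.0], (16, 16, 16), (16, 16))


@pytest.fixture
def geom0():
    """Single 0-degree projection of an 8^3 volume."""
    return TiltGeometry([0.0], (8, 8, 8), (8, 8))


def random_volume(geom, rng):
    return Volume(rng.normal(size=geom.vol_shape))


def random_series(geom, rng):
    return TiltSeries(rng.normal(size=geom.series_shape()), geom.angles_deg)


def smooth_series(geom, rng, sigma=2.0):
    """Random stack smoothed enough for sub-pixel interpolation tests."""
    from scipy import ndimage

    imgs = ndimage.gaussian_filter(
        rng.normal(size=geom.series_shape()), (0, sigma, sigma)
    )
    return TiltSeries(imgs, geom.angles_deg)
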