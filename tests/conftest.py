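import numpy as np
import pytest

from lbikit import CameraModel


@pytest.fixture
def small_camera():
    """Reduced sensor for image-based tests: same pixel pitch, smaller chip."""
    return CameraModel(width=256, height=224, noise_sigma=0.0, n_frames=1)


@pytest.fixture
def noisy_small_camera():
    return CameraModel(width=256, height=224, noise_sigma=0.05, n_frames=10)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def exponential_profile(k=2.0, i0=1000.0, r_max=4.0, n=2001):
    """Analytic exponential decay profile starting at r = 0."""
    from lbikit import AttenuationProfile

    r = np.linspace(0.0, r_max, n)
    return AttenuationProfile(radii=r[1:], intensities=i0 * np.exp(-k * r[1:])), r


@pytest.fixture
def exp_profile():
    """Exponential profile including the r=0 sample so the plateau is I0."""
    from lbikit import AttenuationProfile

    k, i0 = 2.0, 1000.0
    r = np.linspace(0.0, 4.0, 4001)
    return AttenuationProfile(radii=r, intensities=i0 * np.exp(-k * r)), k
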