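import numpy as np
import pytest

from flatpaint.illumination import FieldOfView, IlluminationProfile, calibrate_edge_ratio


@pytest.fixture
def fov256() -> FieldOfView:
    return FieldOfView(n_pixels=256)


@pytest.fixture
def gauss_third(fov256) -> IlluminationProfile:
    """Gaussian beam calibrated to a 1/3 edge ratio on a 256 px FOV."""
    prof = IlluminationProfile(kind="gaussian", gauss_sigma=1.0, center=fov256.center)
    return calibrate_edge_ratio(prof, fov256, 1.0 / 3.0)


@pytest.fixture
def flattop(fov256) -> IlluminationProfile:
    """Flat-top profile whose plateau covers the whole 256 px FOV."""
    return IlluminationProfile(
        kind="flattop", center=fov256.center,
        plateau_radius=0.9 * fov256.width, edge_order=20,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
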