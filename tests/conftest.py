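import numpy as np
import pytest

from laminapipe import phantom
from laminapipe.images import Image3D, Image4D, ImageKind


@pytest.fixture(scope="session")
def small_atlas():
    """Layered phantom atlas on a small grid (session-cached)."""
    anat, atlas = phantom.make_layered_phantom((64, 40, 3), n_layers=5, seed=7)
    return anat, atlas


@pytest.fixture(scope="session")
def textured_volume():
    """Feature-rich 3D volume for registration fixtures."""
    rng = np.random.default_rng(42)
    from scipy import ndimage

    return ndimage.gaussian_filter(rng.normal(0, 1, (32, 32, 16)), 2.0)


@pytest.fixture(scope="session")
def textured_slice():
    """Feature-rich 2D slice (as (nx, ny, 1) volume) for non-rigid fixtures."""
    rng = np.random.default_rng(43)
    from scipy import ndimage

    return ndimage.gaussian_filter(rng.normal(0, 1, (64, 64, 1)), 1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_series(data, tr_s=1.0, pe_axis=1):
    return Image4D(np.asarray(data, float), np.eye(4), tr_s=tr_s, pe_axis=pe_axis)


@pytest.fixture(scope="session")
def quiet_phantom():
    """Motion- and distortion-free phantom truth with modest noise."""
    return phantom.default_phantom(
        (48, 32, 2), n_frames=150, seed=5, with_motion=False, with_fieldmap=False
    )
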