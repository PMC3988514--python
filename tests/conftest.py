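import numpy as np
import pytest

from zharmon import (
    CameraModel,
    make_hoffman_like,
    make_normal_brain,
    make_pool,
)

SHAPE32 = (32, 32, 32)
VOXEL = (3.5, 3.5, 3.5)


@pytest.fixture(scope="session")
def hoffman32():
    return make_hoffman_like(SHAPE32, VOXEL)


@pytest.fixture(scope="session")
def pool32():
    return make_pool(SHAPE32, VOXEL)


@pytest.fixture(scope="session")
def brain32(hoffman32):
    return hoffman32.brain_mask


@pytest.fixture(scope="session")
def normal32():
    return make_normal_brain(SHAPE32, VOXEL)


@pytest.fixture()
def noisefree_camera():
    """A camera with no blur, no filter, no noise: the identity chain."""
    return CameraModel(
        camera_id="ideal",
        psf_fwhm_mm=0.0,
        butterworth_cutoff_cyc_cm=None,
        count_budget=None,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
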