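import numpy as np
import pytest

from radsig.preprocess import Mask3D, Sample, Volume3D


def make_ball_mask(shape, radius, spacing=(1.0, 1.0, 1.0)):
    center = (np.array(shape) - 1) / 2.0
    grids = np.indices(shape).astype(float)
    d2 = sum(((grids[k] - center[k])) ** 2 for k in range(3))
    return Mask3D((d2 <= radius**2).astype(np.uint8), spacing)


def make_phantom(shape=(16, 16, 16), radius=5.0, seed=0, spacing=(1.0, 1.0, 1.0)):
    """Small random phantom: Gaussian noise volume + centered ball ROI."""
    rng = np.random.default_rng(seed)
    vol = Volume3D(rng.standard_normal(shape), spacing)
    mask = make_ball_mask(shape, radius, spacing)
    return vol, mask


@pytest.fixture
def phantom():
    return make_phantom()


@pytest.fixture
def phantom_sample(phantom):
    vol, mask = phantom
    return Sample("p0", vol, mask, label="high", group="training")
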