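import numpy as np
import pytest

from deltarad.imaging import ImageVolume, ROIMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_levels(rng, shape, n_levels, mask_prob=0.8):
    """Random level grid with 0 marking out-of-mask voxels; guarantees at
    least two in-mask voxels."""
    levels = rng.integers(1, n_levels + 1, size=shape)
    mask = rng.random(shape) < mask_prob
    out = np.where(mask, levels, 0).astype(np.int32)
    if (out > 0).sum() < 2:
        out.flat[:2] = [1, n_levels]
    return out


def make_volume(values, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(np.asarray(values, dtype=float), spacing)


def make_mask(values, spacing=(1.0, 1.0, 1.0)):
    return ROIMask(np.asarray(values) > 0, spacing)


@pytest.fixture
def small_phantom():
    """8x8x4 noisy volume with a full mask, for preprocessing tests."""
    g = np.random.default_rng(7)
    vals = 100 + 5 * g.standard_normal((8, 8, 4))
    return make_volume(vals), make_mask(np.ones((8, 8, 4)))
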