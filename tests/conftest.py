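import numpy as np
import pytest

from strokesep.image import ImageSlice, ROIMask
from strokesep.phantom import PhantomSpec, generate_head_slice


def random_roi(rng, max_side=8, max_levels=4):
    """Small random gray-level grid + mask with at least 2 foreground pixels."""
    h = int(rng.integers(2, max_side + 1))
    w = int(rng.integers(2, max_side + 1))
    levels = rng.integers(1, max_levels + 1, size=(h, w))
    mask = rng.random((h, w)) < 0.7
    while mask.sum() < 2:
        mask = rng.random((h, w)) < 0.7
    # gray levels outside the mask are irrelevant; renumber so the max level
    # present in the mask bounds the matrix dimension
    levels = np.where(mask, levels, 1)
    return levels.astype(np.int64), mask


@pytest.fixture(scope="session")
def small_phantom():
    """Noise-free 256x256 head slice and brain mask (shared, read-only)."""
    spec = PhantomSpec(image_shape=(256, 256), noise_sd=0.0, asymmetry_jitter=0.0)
    image, brain = generate_head_slice(spec, seed=11)
    return image, brain


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PhantomSpec(image_shape=(256, 256))
    image, brain = generate_head_slice(spec, seed=11)
    return image, brain
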