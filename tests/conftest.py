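import numpy as np
import pytest

from wsgrade.pipeline import extract_features_table
from wsgrade.preprocess import MeatMask, EnhancedImage
from wsgrade.synthetic import generate_dataset

STRONG_SEED = 11
OVERLAP_SEED = 13


@pytest.fixture(scope="session")
def strong_dataset():
    """120 well-separated synthetic images (20 samples/class, 2 captures)."""
    return generate_dataset(20, STRONG_SEED, profile="strong")


@pytest.fixture(scope="session")
def strong_features(strong_dataset):
    images, _ = strong_dataset
    return extract_features_table(images)


@pytest.fixture(scope="session")
def overlap_features():
    """Feature table for the overlap-tuned set (adjacent MOD/SEV widths)."""
    images, _ = generate_dataset(20, OVERLAP_SEED, profile="overlapping")
    return extract_features_table(images)


def random_enhanced(seed, shape=(16, 16), min_area=60):
    """Random masked raster wrapped as an EnhancedImage (for oracles)."""
    rng = np.random.default_rng(seed)
    mask = np.zeros(shape, dtype=bool)
    while mask.sum() < min_area:
        mask |= rng.random(shape) < 0.4
    gray = np.where(mask, rng.integers(1, 256, shape), 0).astype(np.uint8)
    return EnhancedImage(gray=gray, mask=MeatMask(mask), provenance=[])
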