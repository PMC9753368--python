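import numpy as np
import pytest

from croppainter.preprocess import build_dataset
from croppainter.synthetic import generate_dataset


@pytest.fixture(scope="session")
def small_plants():
    """30 rendered plants as (image_id, rgb, mask) triples."""
    return [(i, r, m) for i, r, m, _ in generate_dataset(30, seed=42)]


@pytest.fixture(scope="session")
def small_manifest(small_plants):
    """A 30-image manifest at 64x64, 20% test split."""
    return build_dataset(small_plants, target_resolution=64,
                         test_fraction=0.2, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
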