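import numpy as np
import pytest
from skimage.draw import disk

from nucfuse.image import TwoChannelImage
from nucfuse.synthetic import generate_scene


def disk_mask(shape, center, radius):
    m = np.zeros(shape, dtype=bool)
    rr, cc = disk(center, radius)
    m[rr, cc] = True
    return m


@pytest.fixture(scope="session")
def small_scene():
    """20-nucleus noisy scene with clumps, shared across tests."""
    return generate_scene(
        20, clump_fraction=0.3, noise_level=5, seed=1, shape=(512, 512)
    )


@pytest.fixture(scope="session")
def clean_scene():
    """Noiseless 10-nucleus scene."""
    return generate_scene(10, noise_level=0, seed=3, shape=(512, 512))


@pytest.fixture()
def disk_image():
    """Single bright disk as a TwoChannelImage + its label map."""
    mask = disk_mask((64, 64), (32, 32), 20.5)
    img = TwoChannelImage(
        green=mask * 100.0 + 1.0, red=mask * 60.0 + 1.0, P=200.0
    )
    return img, mask.astype(np.int32)
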