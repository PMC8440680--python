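import numpy as np
import pytest

from ccfd import EnFaceImage, ImageSynthesisParams, generate_cc_image


@pytest.fixture(scope="session")
def centered_image() -> EnFaceImage:
    """Blank 300x300 scan at 20 um/px with the fovea at the image center."""
    return EnFaceImage(np.zeros((300, 300), dtype=np.uint8))


@pytest.fixture(scope="session")
def default_bundle():
    """One synthetic scan at the default 35% target coverage (seed 7)."""
    return generate_cc_image(ImageSynthesisParams(seed=7))


def random_uint8_image(seed: int, shape=(64, 64)) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 256, size=shape, dtype=np.uint8)
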