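import numpy as np
import pytest

from virtualhe import FluorescenceImage, RenderConfig, StainMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20160808)


@pytest.fixture
def he_stains():
    return StainMatrix.he_default()


@pytest.fixture
def linear_config():
    """Render constants with the sRGB transfer disabled."""
    return RenderConfig(apply_gamma=False)


@pytest.fixture
def random_image(rng):
    """Random 16x16 two-channel fluorescence image with a zero-input pixel."""
    data = rng.uniform(0.0, 1.0, size=(16, 16, 2))
    data[0, 0] = 0.0
    return FluorescenceImage(data, channel_labels=["dapi", "eosin"])


def single_pixel(dapi, eosin):
    return FluorescenceImage(
        np.array([[[dapi, eosin]]], dtype=float), channel_labels=["dapi", "eosin"]
    )
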