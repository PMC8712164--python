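import numpy as np
import pytest

from osteotex.image import RadiographImage


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def constant_image():
    return RadiographImage(np.full((16, 16), 128.0))


def make_image(arr):
    return RadiographImage(np.asarray(arr, dtype=float))


@pytest.fixture
def random_image(rng):
    return RadiographImage(rng.integers(0, 256, size=(32, 32)).astype(float))
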