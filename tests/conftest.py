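import numpy as np
import pytest

from tvclahe.imagio import GrayImage
from tvclahe.phantom import PhantomParams, generate_phantom


def rand_image(rng: np.random.Generator, h: int = 32, w: int = 32,
               bit_depth: int = 8) -> GrayImage:
    hi = (1 << bit_depth) - 1
    return GrayImage(rng.integers(0, hi + 1, (h, w)), bit_depth)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240817)


@pytest.fixture(scope="session")
def small_phantom_params() -> PhantomParams:
    """A reduced canvas for fast unit tests (not the battery geometry)."""
    return PhantomParams(height=120, width=160, canal_width=6.0,
                         blur_sigma=1.5, seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_phantom_params):
    return generate_phantom(small_phantom_params)
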