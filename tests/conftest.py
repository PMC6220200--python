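import numpy as np
import pytest

from femurseg.core_io import LabelMask
from femurseg.phantom import PhantomParams, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_params():
    """Desk-scale phantom parameters for fast tests (24 mm cube-ish grid)."""
    return PhantomParams(
        grid_shape=(48, 48, 16),
        spacing=(1.0, 1.0, 3.0),
        head_radius=9.0, neck_radius=5.0, neck_length=10.0,
        shaft_radius=6.0, shaft_length=14.0, neck_shaft_angle=130.0,
        noise_sd=0.05, trabecular_amplitude=0.08,
    )


@pytest.fixture(scope="session")
def small_phantom(small_params):
    return generate_phantom(small_params, seed=0)


def random_mask_pair(rng, shape=(8, 8, 8), p=0.3, spacing=(1.0, 1.0, 1.0)):
    a = (rng.random(shape) < p).astype(np.uint8)
    b = (rng.random(shape) < p).astype(np.uint8)
    return (LabelMask(a, spacing), LabelMask(b, spacing))


def nonempty_random_mask(rng, shape=(8, 8, 8), p=0.3, spacing=(1.0, 1.0, 1.0)):
    while True:
        m = (rng.random(shape) < p).astype(np.uint8)
        if m.any():
            return LabelMask(m, spacing)
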