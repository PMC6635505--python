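import numpy as np
import pytest

from femvox.calib import DensityImage
from femvox.phantom import default_spec, generate_phantom


@pytest.fixture(scope="session")
def small_spec():
    """Geometrically scaled femur generated at 1 mm spacing: small enough for
    repeated pipeline runs, large enough that the 3 mm model resolves the
    neck cortex asymmetry."""
    return default_spec(scale=0.55, voxel_spacing=(1.0, 1.0, 1.0), rng_seed=1)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture
def uniform_image():
    def make(value=200.0, shape=(6, 6, 6), spacing=(1.0, 1.0, 1.0), unit="mgHA_cm3"):
        return DensityImage(values=np.full(shape, float(value)),
                            spacing=spacing, unit=unit)

    return make
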