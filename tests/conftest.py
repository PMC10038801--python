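import numpy as np
import pytest

from p2t.materials import get_material, uniform_phantom
from p2t.spectrum import monoenergetic


@pytest.fixture
def rng():
    return np.random.default_rng(20241109)


@pytest.fixture
def water_phantom():
    """20 x 20 cm uniform water square, 2 mm voxels."""
    return uniform_phantom("water", half_size=10.0)


@pytest.fixture
def water_disk_phantom():
    """Water disk (radius 8 cm) in air on a 20 x 20 cm grid."""
    return uniform_phantom("water", half_size=10.0, disk_radius=8.0)


@pytest.fixture
def mono5_water_phantom():
    """Uniform water with a single-line 5 MeV spectrum (analytic checks)."""
    ph = uniform_phantom("water", half_size=10.0)
    ph.spectrum = monoenergetic(5.0)
    return ph


@pytest.fixture
def water():
    return get_material("water")
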