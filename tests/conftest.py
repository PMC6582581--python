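import numpy as np
import pytest

from dosemass.io_formats.types import Mask, VoxelGrid


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def unit_grid():
    """4x4x4 grid of 7.0 with spacing (1, 1, 3) mm."""
    return VoxelGrid(np.full((4, 4, 4), 7.0), (1.0, 1.0, 3.0), (0.0, 0.0, 0.0), unit="1")


def make_dose(values, spacing=(10.0, 10.0, 10.0)):
    """Dose grid helper: 1 cm^3 voxels by default."""
    return VoxelGrid(np.asarray(values, dtype=float), spacing, (0.0, 0.0, 0.0), unit="Gy")


def make_mask(values, spacing=(10.0, 10.0, 10.0)):
    return Mask(np.asarray(values, dtype=bool), spacing, (0.0, 0.0, 0.0))


@pytest.fixture
def three_voxel_case():
    """The worked micro-example: 1 cm^3 voxels, doses 10/20/30 Gy,
    densities 0.1/0.2/0.3 g/cm^3 on a 3x1x1 grid."""
    dose = make_dose(np.array([10.0, 20.0, 30.0]).reshape(3, 1, 1))
    density = VoxelGrid(
        np.array([0.1, 0.2, 0.3]).reshape(3, 1, 1), (10.0, 10.0, 10.0), unit="g/cm3"
    )
    mask = make_mask(np.ones((3, 1, 1)))
    return dose, density, mask
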