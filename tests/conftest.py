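import numpy as np
import pytest

from vdpkit import CavityMask, PhantomSpec, VolumeGrid


@pytest.fixture
def hundred_voxel_pair():
    """A 100-voxel cavity: 10 defect voxels at 0, 90 ventilated at 1.

    Laid out in a 5x5x4 grid; the whole grid is cavity.
    """
    vals = np.array([0.0] * 10 + [1.0] * 90).reshape(5, 5, 4)
    vol = VolumeGrid(vals, voxel_spacing=(4.42, 4.42, 4.42), modality="SPECT")
    cav = CavityMask(np.ones((5, 5, 4), dtype=bool), voxel_spacing=(4.42, 4.42, 4.42))
    return vol, cav


@pytest.fixture
def uniform_pair():
    """A uniform-intensity cavity (value 3.0) on a 4x4x4 grid."""
    vol = VolumeGrid(np.full((4, 4, 4), 3.0), voxel_spacing=(1, 1, 1))
    cav = CavityMask(np.ones((4, 4, 4), dtype=bool), voxel_spacing=(1, 1, 1))
    return vol, cav


def small_phantom_spec(**overrides) -> PhantomSpec:
    """A desk-scale phantom spec for unit tests (coarser grid, smaller lungs)."""
    kwargs = dict(
        grid_shape=(48, 48, 32),
        truth_spacing=3.0,
        lung_semiaxes=(20.0, 35.0, 28.0),
        lung_gap=12.0,
        defect_fraction_target=0.15,
        defect_count=3,
        seed=0,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture
def small_spec():
    return small_phantom_spec()
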