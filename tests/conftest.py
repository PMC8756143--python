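import numpy as np
import pytest

from ecconnseg import AxisFrame, ROIMask, SyntheticCohortSpec, VolumeGrid


def centered_grid(shape=(10, 10, 10), voxel_mm=1.0, data=None):
    """Grid whose world origin is at the center of the volume (RAS mm)."""
    shape = tuple(shape)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * (np.array(shape) - 1) / 2.0
    if data is None:
        data = np.zeros(shape)
    return VolumeGrid(data=data, affine=affine)


@pytest.fixture
def frame():
    return AxisFrame()


@pytest.fixture
def tiny_spec():
    """Small, fast synthetic cohort: 2 participants, no jitter, no count noise."""
    return SyntheticCohortSpec(
        n_participants=2,
        grid_shape=(32, 40, 24),
        ec_extent_mm=(10.0, 10.0, 8.0),
        ec_center_lateral_mm=9.0,
        theta_true=0.0,
        subject_jitter_deg=0.0,
        count_noise=False,
        seed=7,
    )


def ball_mask(shape=(12, 12, 12), radius_mm=4.0, center_world=(0.0, 0.0, 0.0),
              voxel_mm=1.0, name="EC"):
    grid = centered_grid(shape, voxel_mm)
    world = grid.world_coordinates()
    inside = np.linalg.norm(world - np.asarray(center_world), axis=-1) <= radius_mm
    return ROIMask(grid=grid.with_data(inside.astype(np.uint8)), name=name)
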