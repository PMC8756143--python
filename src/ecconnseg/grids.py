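"""Volume data model, NIfTI I/O and world-coordinate geometry.

Everything downstream (connectivity maps, masks, label maps) is carried by a
:class:`VolumeGrid`: a 3D scalar array plus a 4x4 affine mapping 0-based voxel
indices (voxel-center convention) to world millimetres.  The world frame is
RAS-like: +x = right, +y = anterior, +z = superior.  Anatomical directions —
the posterior-anterior (PA) axis, the per-hemisphere medial-lateral (ML) axis
and the interhemispheric midline — live in an :class:`AxisFrame` and are
configurable, because the PA axis of interest (the long axis of the
hippocampus) need not coincide with a coordinate axis of the template space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from nibabel.affines import apply_affine

from .errors import (
    BoundsError,
    DimensionalityError,
    EmptyMaskError,
    FormatError,
    GeometryError,
)

__all__ = [
    "VolumeGrid",
    "ROIMask",
    "AxisFrame",
    "read_volume",
    "write_volume",
    "split_hemispheres",
    "voxel_to_world",
]

_ORTHO_TOL = 1e-6


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D scalar field with an affine to world (mm) coordinates.

    Parameters
    ----------
    data
        3D array of scalars (connectivity values, mask bits or labels).
    affine
        4x4 invertible voxel-index -> world-mm transform, voxel-center
        convention with 0-based indices.
    axis_convention
        Label stating the world-axis meaning; only ``"RAS"`` is produced by
        this package but the field travels with the data.
    """

    data: np.ndarray
    affine: np.ndarray
    axis_convention: str = "RAS"

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        affine = np.asarray(self.affine, dtype=float)
        if data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D volume, got {data.ndim} dimensions"
            )
        if min(data.shape) < 1:
            raise DimensionalityError("every axis must have extent >= 1")
        if affine.shape != (4, 4):
            raise GeometryError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise GeometryError("affine is singular")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """mm per voxel along each array axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        """Same geometry, new values."""
        return replace(self, data=np.asarray(data))

    def world_coordinates(self) -> np.ndarray:
        """World-mm coordinates of every voxel center, shape ``shape + (3,)``."""
        idx = np.indices(self.shape).transpose(1, 2, 3, 0)
        return apply_affine(self.affine, idx)

    def same_grid(self, other: "VolumeGrid", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )


@dataclass(frozen=True)
class ROIMask:
    """A binary region-of-interest on a :class:`VolumeGrid`.

    ``name`` identifies the region (EC, presubiculum, dCA1pSub, RSC, OFC);
    ``hemisphere`` is ``"left"``, ``"right"`` or ``"both"``.
    """

    grid: VolumeGrid
    name: str
    hemisphere: str = "both"

    def __post_init__(self) -> None:
        values = np.unique(self.grid.data)
        if not np.isin(values, (0, 1)).all():
            raise FormatError(f"mask '{self.name}' has values outside {{0,1}}")

    @property
    def indicator(self) -> np.ndarray:
        return self.grid.data.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.indicator.sum())

    def require_nonempty(self) -> None:
        if self.n_voxels == 0:
            raise EmptyMaskError(f"mask '{self.name}' is empty")


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError(f"{what} must be nonzero")
    return v / n


@dataclass(frozen=True)
class AxisFrame:
    """Anatomical axes and midline in world coordinates.

    ``pa_axis`` points posterior -> anterior.  ``ml_axis(hemisphere)`` points
    medial -> lateral, i.e. away from the midplane, so it differs in sign
    between hemispheres.  The midline is the plane
    ``dot(x, midline_normal) == midline_offset``; world points with positive
    signed distance are in the right hemisphere, non-positive (including the
    measure-zero on-plane case) in the left.
    """

    pa_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    ml_axis_right: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0])
    )
    midline_normal: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0])
    )
    midline_offset: float = 0.0

    def __post_init__(self) -> None:
        pa = _unit(self.pa_axis, "pa_axis")
        ml = _unit(self.ml_axis_right, "ml_axis")
        normal = _unit(self.midline_normal, "midline_normal")
        if abs(np.dot(pa, ml)) > _ORTHO_TOL:
            raise GeometryError("pa_axis and ml_axis must be orthogonal")
        object.__setattr__(self, "pa_axis", pa)
        object.__setattr__(self, "ml_axis_right", ml)
        object.__setattr__(self, "midline_normal", normal)

    def ml_axis(self, hemisphere: str) -> np.ndarray:
        """Medial->lateral unit vector for one hemisphere."""
        if hemisphere == "right":
            return self.ml_axis_right
        if hemisphere == "left":
            return -self.ml_axis_right
        raise GeometryError(f"unknown hemisphere {hemisphere!r}")

    def signed_distance(self, world_points: np.ndarray) -> np.ndarray:
        return np.asarray(world_points) @ self.midline_normal - self.midline_offset

    def hemisphere_selectors(self, grid: VolumeGrid) -> dict[str, np.ndarray]:
        """Boolean voxel selectors partitioning the grid into hemispheres.

        Voxel centers exactly on the midplane go to the left hemisphere.
        """
        signed = self.signed_distance(grid.world_coordinates())
        right = signed > 0
        return {"left": ~right, "right": right}


def read_volume(path) -> VolumeGrid:
    """Read a NIfTI-1 volume into a :class:`VolumeGrid`.

    Raises :class:`FormatError` for unparseable files and
    :class:`DimensionalityError` for anything but a 3D image.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of types here
        raise FormatError(f"could not read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path}: expected a 3D volume, got shape {data.shape}"
        )
    return VolumeGrid(data=data, affine=np.asarray(img.affine))


def write_volume(grid: VolumeGrid, path) -> None:
    """Write a :class:`VolumeGrid` as NIfTI-1."""
    data = grid.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, grid.affine), str(path))


def voxel_to_world(grid: VolumeGrid, index) -> np.ndarray:
    """World-mm coordinate of a voxel center, with bounds checking."""
    index = np.asarray(index)
    if index.shape != (3,):
        raise BoundsError(f"index must be a 3-vector, got shape {index.shape}")
    if (index < 0).any() or (index >= np.array(grid.shape)).any():
        raise BoundsError(f"index {tuple(index)} out of bounds for {grid.shape}")
    return apply_affine(grid.affine, index)


def split_hemispheres(mask: ROIMask, frame: AxisFrame) -> tuple[ROIMask, ROIMask]:
    """Partition a mask into (left, right) by the frame's midline.

    The outputs partition the input exactly; an empty input raises
    :class:`EmptyMaskError`, but an empty *output* hemisphere is legal.
    """
    mask.require_nonempty()
    selectors = frame.hemisphere_selectors(mask.grid)
    out = []
    for hemi in ("left", "right"):
        data = (mask.indicator & selectors[hemi]).astype(np.uint8)
        out.append(
            ROIMask(grid=mask.grid.with_data(data), name=mask.name, hemisphere=hemi)
        )
    return out[0], out[1]
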