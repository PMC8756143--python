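"""Normalization, thresholding, smoothing and aggregation of connectivity maps.

The per-participant pipeline is: divide each hemisphere's voxel-wise
connection probabilities by that hemisphere's maximum (so every hemisphere's
map tops out at 1), then zero everything below a small threshold (default
0.01) to suppress spurious connections.  At the group level, the normalized
individual maps are averaged, smoothed with a small Gaussian kernel and then
thresholded before segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import (
    AlignmentError,
    DegenerateMapError,
    ParameterError,
)
from .grids import AxisFrame, ROIMask, VolumeGrid

__all__ = [
    "ConnectivityMap",
    "GroupMap",
    "normalize_per_hemisphere",
    "threshold_map",
    "group_average",
    "smooth_gaussian",
    "combine_seed_maps",
]

DEFAULT_THRESHOLD = 0.01
DEFAULT_KERNEL_MM = 1.0


@dataclass(frozen=True)
class ConnectivityMap:
    """Voxel-wise probability of connection between EC voxels and one seed.

    The volume spans both hemispheres; hemisphere-wise operations take an
    :class:`AxisFrame`.  ``ec_mask`` (optional) records the support: values
    are zero outside it, and normalization treats a nonempty-support
    hemisphere with no signal as an error rather than silently passing it on.
    """

    grid: VolumeGrid
    seed_region: str
    participant_id: str | None = None
    hemisphere: str = "both"
    ec_mask: ROIMask | None = None
    normalized: bool = False
    thresholded_at: float | None = None

    def __post_init__(self) -> None:
        if (np.asarray(self.grid.data) < 0).any():
            raise ParameterError("connectivity values must be >= 0")
        if self.ec_mask is not None:
            outside = ~self.ec_mask.indicator
            if np.any(np.asarray(self.grid.data)[outside] != 0):
                raise ParameterError("connectivity map is nonzero outside the EC mask")

    def with_data(self, data: np.ndarray, **changes) -> "ConnectivityMap":
        return replace(self, grid=self.grid.with_data(data), **changes)


@dataclass(frozen=True)
class GroupMap:
    """Across-participant average connectivity for one seed (or combination).

    ``ec_mask`` records the EC support of the underlying individual maps so
    that group segmentation can clip the smoothing halo back to the EC.
    """

    grid: VolumeGrid
    seed_region: str
    n_participants: int
    smoothed_mm: float | None = None
    ec_mask: ROIMask | None = None

    def __post_init__(self) -> None:
        if (np.asarray(self.grid.data) < 0).any():
            raise ParameterError("group map values must be >= 0")

    def with_data(self, data: np.ndarray, **changes) -> "GroupMap":
        return replace(self, grid=self.grid.with_data(data), **changes)


def _support_selectors(cmap: ConnectivityMap, frame: AxisFrame):
    """Per-hemisphere boolean support of a map (EC mask if present)."""
    selectors = frame.hemisphere_selectors(cmap.grid)
    if cmap.ec_mask is not None:
        support = cmap.ec_mask.indicator
    else:
        support = cmap.grid.data > 0
    return {h: selectors[h] & support for h in ("left", "right")}


def normalize_per_hemisphere(
    cmap: ConnectivityMap, frame: AxisFrame | None = None
) -> ConnectivityMap:
    """Scale each hemisphere's values so its maximum becomes exactly 1.

    Hemispheres are independent: the same raw value can map to different
    normalized values left and right.  A hemisphere whose support is nonempty
    but whose values are all zero indicates a failed connectivity computation
    and raises :class:`DegenerateMapError`; an empty hemisphere is skipped.
    """
    frame = frame or AxisFrame()
    data = cmap.grid.data.astype(float).copy()
    for hemi, sel in _support_selectors(cmap, frame).items():
        if not sel.any():
            continue
        peak = data[sel].max()
        if peak <= 0:
            raise DegenerateMapError(
                f"{cmap.seed_region}: all-zero {hemi} hemisphere with nonempty support"
            )
        data[sel] = data[sel] / peak
    return cmap.with_data(data, normalized=True)


def threshold_map(cmap, threshold: float = DEFAULT_THRESHOLD):
    """Zero values below ``threshold``; values >= threshold are kept unchanged.

    Accepts a :class:`ConnectivityMap` (records ``thresholded_at``) or a
    :class:`GroupMap`.
    """
    if not 0 <= threshold <= 1:
        raise ParameterError("threshold must be in [0, 1]")
    data = cmap.grid.data.copy()
    data[data < threshold] = 0.0
    if isinstance(cmap, ConnectivityMap):
        return cmap.with_data(data, thresholded_at=threshold)
    return cmap.with_data(data)


def group_average(maps: list[ConnectivityMap]) -> GroupMap:
    """Voxel-wise mean of one seed's maps across participants."""
    if not maps:
        raise ParameterError("group_average needs at least one map")
    first = maps[0]
    for m in maps[1:]:
        if not m.grid.same_grid(first.grid):
            raise AlignmentError("maps do not share a grid")
        if m.seed_region != first.seed_region:
            raise AlignmentError(
                f"mixed seed regions: {m.seed_region} vs {first.seed_region}"
            )
    mean = np.mean([m.grid.data for m in maps], axis=0)
    return GroupMap(
        grid=first.grid.with_data(mean),
        seed_region=first.seed_region,
        n_participants=len(maps),
        ec_mask=first.ec_mask,
    )


def smooth_gaussian(gmap: GroupMap, kernel_mm: float = DEFAULT_KERNEL_MM,
                    fwhm: bool = False) -> GroupMap:
    """Gaussian smoothing with a kernel given in millimetres.

    ``kernel_mm`` is the Gaussian sigma by default; pass ``fwhm=True`` to
    interpret it as full width at half maximum instead.  The kernel is
    converted to voxel units per axis via the voxel size.  Zero-padded
    boundaries: total mass over the grid is conserved as long as the signal
    does not touch the edges (the EC sits well inside the grid).
    """
    if kernel_mm <= 0:
        raise ParameterError("kernel_mm must be > 0")
    sigma_mm = kernel_mm / 2.3548200450309493 if fwhm else kernel_mm
    sigma_vox = sigma_mm / gmap.grid.voxel_size
    smoothed = gaussian_filter(gmap.grid.data.astype(float), sigma=sigma_vox,
                               mode="constant", cval=0.0)
    return gmap.with_data(smoothed, smoothed_mm=kernel_mm)


def combine_seed_maps(map_a, map_b):
    """Voxel-wise mean of two maps (e.g. presubiculum + RSC), same type out."""
    if not map_a.grid.same_grid(map_b.grid):
        raise AlignmentError("maps do not share a grid")
    mean = (map_a.grid.data.astype(float) + map_b.grid.data.astype(float)) / 2.0
    combined_name = f"{map_a.seed_region}+{map_b.seed_region}"
    if isinstance(map_a, GroupMap):
        return GroupMap(
            grid=map_a.grid.with_data(mean),
            seed_region=combined_name,
            n_participants=map_a.n_participants,
            smoothed_mm=map_a.smoothed_mm,
            ec_mask=map_a.ec_mask,
        )
    return map_a.with_data(mean, seed_region=combined_name)
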