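"""Synthetic EC connectivity cohorts with known ground truth.

Real voxel-wise connectivity maps come from probabilistic tractography between
an entorhinal cortex (EC) seed mask and four target regions: presubiculum and
retrosplenial cortex (RSC), whose connectivity is strongest in posterior EC
and defines the MEC homologue, and distal-CA1/proximal-subiculum (dCA1pSub)
and lateral orbitofrontal cortex (OFC), strongest anteriorly and defining the
LEC homologue.  This module emulates those maps directly: a mirror-symmetric
curved-slab EC mask per hemisphere, opposed linear connectivity ramps along a
configurable direction in the PA-ML plane, and binomial count noise mimicking
streamline counting with a fixed number of samples per seed voxel.  It is an
emulation of the connectivity *structure*, not a simulation of tractography:
there is no streamline propagation, path-length dependence or exclusion
masking.

The ground-truth parameter of interest is ``theta_true``, the angle (degrees)
of the connectivity-gradient direction in the PA-ML plane: 0 means a pure
posterior-anterior gradient, 90 a pure medial-lateral one.  Downstream, the
MEC->LEC center-of-gravity vector of a noise-free segmentation is parallel to
this direction, which is what makes parameter recovery testable end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import GeometryError, ParameterError
from .grids import AxisFrame, ROIMask, VolumeGrid
from .processing import ConnectivityMap

__all__ = [
    "SyntheticCohortSpec",
    "SubjectConnectivity",
    "MEC_SEEDS",
    "LEC_SEEDS",
    "SEED_REGIONS",
    "make_ec_mask",
    "make_gradient_field",
    "sample_counts",
    "make_cohort",
]

MEC_SEEDS = ("presubiculum", "RSC")
LEC_SEEDS = ("dCA1pSub", "OFC")
SEED_REGIONS = MEC_SEEDS + LEC_SEEDS

# Seeds whose gradient direction gets the extra pair offset (cortical seeds).
_CORTICAL_SEEDS = ("RSC", "OFC")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a synthetic connectivity cohort.

    Defaults mirror the study conditions being emulated: 35 participants,
    250,000 tractography samples per seed voxel, and an EC-sized slab on a
    1 mm desk-scale grid.  ``theta_true`` defaults to 45 degrees — a border
    oriented equally toward the PA and ML axes, the qualitative outcome of the
    combined-seed segmentation being emulated.

    Parameters
    ----------
    n_participants
        Cohort size.
    grid_shape, voxel_size_mm
        Analysis grid; the affine centers the grid on the midline.
    ec_extent_mm
        EC slab extent (ML, PA, SI) in mm per hemisphere.  The mask is an
        elliptical disk in the PA-ML plane (axes = ML and PA extents)
        extruded along SI.  The default extents are equal, giving a circular
        cross-section: that is what makes the center-of-gravity estimator of
        the border direction exact — for an anisotropic cross-section the
        CoG-difference direction is biased toward the long axis, which is a
        property of the estimator, not of the noise.
    ec_center_lateral_mm
        Distance of each slab center from the midline.
    ec_curvature_mm
        Peak medial-lateral shear of the slab over its PA extent; a
        volume-preserving bend that makes the mask EC-like rather than
        disk-like.  Nonzero values break the rotational symmetry the exact
        recovery relies on; default 0.
    theta_true
        Ground-truth gradient angle in the PA-ML plane, degrees in [0, 90].
    gradient_contrast
        Ratio of max to min connection probability along the gradient.
    p_max
        Peak connection probability.
    n_samples
        Streamline samples per voxel for binomial count noise.
    count_noise
        Disable to emit the exact probability ramps (the noise-free limit).
    subject_jitter_deg
        SD of the per-participant rotation of the gradient direction.
    pair_offset_deg
        Extra rotation (toward PA) of the cortical seeds' gradient (RSC/OFC)
        relative to the hippocampal seeds, emulating the seed-pair differences
        in border orientation.
    seed
        Master RNG seed.
    """

    n_participants: int = 35
    grid_shape: tuple[int, int, int] = (48, 64, 48)
    voxel_size_mm: float = 1.0
    ec_extent_mm: tuple[float, float, float] = (14.0, 14.0, 10.0)
    ec_center_lateral_mm: float = 15.0
    ec_curvature_mm: float = 0.0
    theta_true: float = 45.0
    gradient_contrast: float = 3.0
    p_max: float = 0.5
    n_samples: int = 250_000
    count_noise: bool = True
    subject_jitter_deg: float = 5.0
    pair_offset_deg: float = 0.0
    seed: int = 0
    frame: AxisFrame = field(default_factory=AxisFrame)

    def __post_init__(self) -> None:
        if not 0 < self.p_max <= 1:
            raise ParameterError("p_max must be in (0, 1]")
        if self.n_samples < 1:
            raise ParameterError("n_samples must be >= 1")
        if self.n_participants < 1:
            raise ParameterError("n_participants must be >= 1")
        if not 0 <= self.theta_true <= 90:
            raise ParameterError("theta_true must be in [0, 90] degrees")
        if self.gradient_contrast < 1:
            raise ParameterError("gradient_contrast must be >= 1")

    def make_grid(self) -> VolumeGrid:
        """Empty grid with the midline through the center of the volume."""
        shape = tuple(int(s) for s in self.grid_shape)
        vs = float(self.voxel_size_mm)
        affine = np.diag([vs, vs, vs, 1.0])
        # translate so the world origin sits at the grid center
        affine[:3, 3] = -vs * (np.array(shape) - 1) / 2.0
        return VolumeGrid(data=np.zeros(shape), affine=affine)

    def participant_rng(self, index: int) -> np.random.Generator:
        """Independent stream per participant, stable under reordering."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(index,))
        )


@dataclass(frozen=True)
class SubjectConnectivity:
    """One participant's four connectivity maps plus generation provenance."""

    participant_id: str
    maps: dict  # seed region -> ConnectivityMap (both hemispheres, one grid)
    ec_mask: ROIMask
    realized_theta_deg: float
    spec: SyntheticCohortSpec

    def __post_init__(self) -> None:
        for seed, cmap in self.maps.items():
            if (cmap.grid.data < 0).any() or (cmap.grid.data > 1).any():
                raise ParameterError(f"map '{seed}' has values outside [0,1]")


def make_ec_mask(spec: SyntheticCohortSpec) -> ROIMask:
    """Mirror-symmetric left+right EC slab masks on the spec's grid.

    Each hemisphere's mask is an elliptical disk in the PA-ML plane (axes
    given by the ML and PA extents), extruded over the SI extent and
    optionally bent by a PA-dependent medial-lateral shear of peak
    ``ec_curvature_mm``.  The shear preserves volume, so the voxel count
    stays close to the analytic volume ``pi * (ml/2) * (pa/2) * si`` divided
    by the voxel volume.
    """
    ml_e, pa_e, si_e = (float(v) for v in spec.ec_extent_mm)
    if min(ml_e, pa_e, si_e) <= 0:
        raise GeometryError("EC extent must be positive along every axis")
    grid = spec.make_grid()
    world = grid.world_coordinates()
    frame = spec.frame
    pa = world @ frame.pa_axis
    si_axis = np.cross(frame.midline_normal, frame.pa_axis)
    si = world @ si_axis
    lateral = frame.signed_distance(world)  # signed ML position, + = right

    half_extent = np.array([ml_e, pa_e, si_e]) / 2.0
    needed = np.array(
        [spec.ec_center_lateral_mm + half_extent[0], half_extent[1], half_extent[2]]
    )
    world_half = (np.array(grid.shape) * grid.voxel_size) / 2.0
    if (needed > world_half).any():
        raise GeometryError(
            f"EC geometry (needs {needed} mm half-extent) exceeds grid "
            f"({world_half} mm half-extent)"
        )

    # parabolic ML shear: 0 at the PA center, ec_curvature_mm at the ends
    pa_rel = pa / half_extent[1]
    shear = spec.ec_curvature_mm * np.clip(pa_rel, -1, 1) ** 2
    ml_rel = (np.abs(lateral) - (spec.ec_center_lateral_mm + shear)) / half_extent[0]
    inside = (
        (ml_rel**2 + pa_rel**2 <= 1.0)
        & (np.abs(si) <= half_extent[2])
    )
    return ROIMask(grid=grid.with_data(inside.astype(np.uint8)), name="EC")


def make_gradient_field(
    mask: ROIMask,
    direction: np.ndarray,
    contrast: float,
    p_max: float,
) -> ConnectivityMap:
    """Linear connection-probability ramp along ``direction`` over a mask.

    Over the mask's voxels the value rises linearly with the world-coordinate
    projection onto ``direction``, rescaled so the maximum is ``p_max`` and
    the minimum ``p_max / contrast``; outside the mask the field is zero.
    ``contrast == 1`` gives a constant field.
    """
    if contrast < 1:
        raise ParameterError("contrast must be >= 1")
    if not 0 < p_max <= 1:
        raise ParameterError("p_max must be in (0, 1]")
    mask.require_nonempty()
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm < 1e-12:
        raise ParameterError("direction must be nonzero")
    direction = direction / norm

    grid = mask.grid
    inside = mask.indicator
    proj = grid.world_coordinates()[inside] @ direction
    lo, hi = proj.min(), proj.max()
    p_min = p_max / contrast
    if hi - lo < 1e-12:  # degenerate support (single plane): constant field
        values = np.full(proj.shape, p_max)
    else:
        values = p_min + (proj - lo) / (hi - lo) * (p_max - p_min)
    data = np.zeros(grid.shape)
    data[inside] = values
    return ConnectivityMap(grid=grid.with_data(data), seed_region="synthetic",
                           ec_mask=mask)


def sample_counts(
    p_field: ConnectivityMap, n_samples: int, rng
) -> ConnectivityMap:
    """Replace each probability with a binomial count fraction k/n.

    Emulates streamline counting: each voxel's probability p becomes
    ``Binomial(n_samples, p) / n_samples``.  ``rng`` is a seed or a numpy
    Generator; results are deterministic given either.
    """
    if n_samples < 1:
        raise ParameterError("n_samples must be >= 1")
    p = p_field.grid.data
    if (p < 0).any() or (p > 1).any():
        raise ParameterError("probabilities must be in [0, 1]")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    noisy = np.zeros_like(p, dtype=float)
    support = p > 0
    noisy[support] = gen.binomial(n_samples, p[support]) / n_samples
    return ConnectivityMap(
        grid=p_field.grid.with_data(noisy),
        seed_region=p_field.seed_region,
        participant_id=p_field.participant_id,
        ec_mask=p_field.ec_mask,
    )


def _rotate_in_pa_ml_plane(frame: AxisFrame, theta_deg: float) -> dict[str, np.ndarray]:
    """Unit gradient direction per hemisphere at angle theta from PA toward ML."""
    t = math.radians(theta_deg)
    out = {}
    for hemi in ("left", "right"):
        out[hemi] = math.cos(t) * frame.pa_axis + math.sin(t) * frame.ml_axis(hemi)
    return out


def _subject_maps(
    spec: SyntheticCohortSpec, mask: ROIMask, index: int
) -> SubjectConnectivity:
    rng = spec.participant_rng(index)
    jitter = float(rng.normal(0.0, spec.subject_jitter_deg)) if spec.subject_jitter_deg > 0 else 0.0
    theta = spec.theta_true + jitter
    selectors = spec.frame.hemisphere_selectors(mask.grid)

    maps: dict[str, ConnectivityMap] = {}
    for seed_name in SEED_REGIONS:
        seed_theta = theta
        if seed_name in _CORTICAL_SEEDS:
            seed_theta -= spec.pair_offset_deg
        directions = _rotate_in_pa_ml_plane(spec.frame, seed_theta)
        sign = -1.0 if seed_name in MEC_SEEDS else 1.0
        data = np.zeros(mask.grid.shape)
        for hemi in ("left", "right"):
            hemi_ind = (mask.indicator & selectors[hemi]).astype(np.uint8)
            if not hemi_ind.any():
                continue
            hemi_mask = ROIMask(grid=mask.grid.with_data(hemi_ind), name="EC",
                                hemisphere=hemi)
            ramp = make_gradient_field(
                hemi_mask, sign * directions[hemi],
                spec.gradient_contrast, spec.p_max,
            )
            data += ramp.grid.data
        clean = ConnectivityMap(
            grid=mask.grid.with_data(data),
            seed_region=seed_name,
            participant_id=f"sub-{index:03d}",
            ec_mask=mask,
        )
        maps[seed_name] = (
            sample_counts(clean, spec.n_samples, rng) if spec.count_noise else clean
        )
    return SubjectConnectivity(
        participant_id=f"sub-{index:03d}",
        maps=maps,
        ec_mask=mask,
        realized_theta_deg=theta,
        spec=spec,
    )


def make_cohort(spec: SyntheticCohortSpec) -> list[SubjectConnectivity]:
    """Generate the full cohort; bit-reproducible from ``spec.seed``."""
    mask = make_ec_mask(spec)
    return [_subject_maps(spec, mask, i) for i in range(spec.n_participants)]


def iter_cohort(spec: SyntheticCohortSpec) -> Iterator[SubjectConnectivity]:
    """Lazy variant of :func:`make_cohort` for memory-lean pipelines."""
    mask = make_ec_mask(spec)
    for i in range(spec.n_participants):
        yield _subject_maps(spec, mask, i)
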