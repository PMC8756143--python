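"""Hard MEC/LEC segmentation and inter-participant variability maps.

Each EC voxel is labeled by winner-take-all comparison of two evidence maps:
MEC where connectivity with the MEC-defining seeds (presubiculum, RSC) beats
connectivity with the LEC-defining seeds (dCA1pSub, OFC), LEC for the
converse, background where neither survives thresholding.  Five approaches
are supported: the four 2x2 seed pairings and a combined approach that
averages each pair's maps before segmenting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, InputError, ParameterError
from .grids import AxisFrame, VolumeGrid
from .processing import (
    DEFAULT_KERNEL_MM,
    DEFAULT_THRESHOLD,
    GroupMap,
    combine_seed_maps,
    normalize_per_hemisphere,
    smooth_gaussian,
    threshold_map,
)

__all__ = [
    "BACKGROUND",
    "MEC",
    "LEC",
    "APPROACHES",
    "SegmentationLabelMap",
    "VariabilityMap",
    "hard_segment",
    "segment_participant",
    "variability_map",
    "segment_group",
]

BACKGROUND, MEC, LEC = 0, 1, 2

# approach name -> (MEC-evidence seed, LEC-evidence seed); None = combined
APPROACHES: dict[str, tuple[str, str] | None] = {
    "presubiculum/dCA1pSub": ("presubiculum", "dCA1pSub"),
    "RSC/OFC": ("RSC", "OFC"),
    "presubiculum/OFC": ("presubiculum", "OFC"),
    "RSC/dCA1pSub": ("RSC", "dCA1pSub"),
    "combined": None,
}


@dataclass(frozen=True)
class SegmentationLabelMap:
    """Per-voxel categorical labels: 0 background, 1 MEC, 2 LEC."""

    grid: VolumeGrid
    approach: str
    level: str = "participant"  # or "group"
    participant_id: str | None = None

    def __post_init__(self) -> None:
        labels = np.unique(self.grid.data)
        if not np.isin(labels, (BACKGROUND, MEC, LEC)).all():
            raise ParameterError(f"labels outside {{0,1,2}}: {labels}")

    def label_indicator(self, label: int) -> np.ndarray:
        return self.grid.data == label


@dataclass(frozen=True)
class VariabilityMap:
    """Voxel-wise count of participants assigning each label."""

    mec_counts: VolumeGrid
    lec_counts: VolumeGrid
    n_participants: int

    def __post_init__(self) -> None:
        mec = self.mec_counts.data
        lec = self.lec_counts.data
        if (mec < 0).any() or (lec < 0).any():
            raise ParameterError("counts must be >= 0")
        if ((mec + lec) > self.n_participants).any():
            raise ParameterError("MEC + LEC counts exceed n_participants")


def hard_segment(
    mec_evidence,
    lec_evidence,
    tie_rule: str = "background",
    tie_rtol: float = 1e-9,
    approach: str = "custom",
    level: str = "participant",
    participant_id: str | None = None,
) -> SegmentationLabelMap:
    """Winner-take-all labeling of two thresholded evidence maps.

    A voxel is MEC where MEC evidence strictly exceeds LEC evidence and is
    positive; LEC for the converse; background where both are zero.  Equal
    positive evidence goes to background by default (``tie_rule =
    "background"``); ``tie_rule = "first"`` awards ties to the MEC map, the
    behavior of first-wins tooling.  A voxel suprathreshold in exactly one
    map is labeled by that map.

    Ties are detected up to a relative tolerance ``tie_rtol``: evidence pairs
    within ``tie_rtol * max(a, b)`` of each other count as equal.  Analytic
    ties (two opposed ramps meeting on a lattice plane) otherwise get broken
    by float rounding, which would hand an entire tie plane to whichever map
    accumulated the smaller error; pass ``tie_rtol=0`` for exact comparison.
    """
    if tie_rule not in ("background", "first"):
        raise ParameterError(f"unknown tie_rule {tie_rule!r}")
    if not mec_evidence.grid.same_grid(lec_evidence.grid):
        raise AlignmentError("evidence maps do not share a grid")
    a = mec_evidence.grid.data
    b = lec_evidence.grid.data
    tol = tie_rtol * np.maximum(np.abs(a), np.abs(b))
    tie = np.abs(a - b) <= tol
    labels = np.full(a.shape, BACKGROUND, dtype=np.int16)
    labels[(a > b) & ~tie & (a > 0)] = MEC
    labels[(b > a) & ~tie & (b > 0)] = LEC
    if tie_rule == "first":
        labels[tie & (a > 0)] = MEC
    return SegmentationLabelMap(
        grid=mec_evidence.grid.with_data(labels),
        approach=approach,
        level=level,
        participant_id=participant_id,
    )


def _evidence_pair(maps: dict, approach: str):
    """Resolve an approach name to (MEC evidence, LEC evidence) inputs."""
    if approach not in APPROACHES:
        raise InputError(
            f"unknown approach {approach!r}; expected one of {sorted(APPROACHES)}"
        )
    pair = APPROACHES[approach]
    needed = ("presubiculum", "RSC", "dCA1pSub", "OFC") if pair is None else pair
    missing = [s for s in needed if s not in maps]
    if missing:
        raise InputError(f"approach {approach!r} needs missing seed map(s) {missing}")
    if pair is None:
        return (
            combine_seed_maps(maps["presubiculum"], maps["RSC"]),
            combine_seed_maps(maps["dCA1pSub"], maps["OFC"]),
        )
    return maps[pair[0]], maps[pair[1]]


def segment_participant(
    subject,
    approach: str,
    threshold: float = DEFAULT_THRESHOLD,
    frame: AxisFrame | None = None,
    tie_rule: str = "background",
) -> SegmentationLabelMap:
    """Full per-participant pipeline: normalize, threshold, hard-segment.

    For the combined approach, each seed pair's normalized maps are averaged
    before thresholding.
    """
    frame = frame or AxisFrame()
    normalized = {
        seed: normalize_per_hemisphere(cmap, frame)
        for seed, cmap in subject.maps.items()
    }
    mec_ev, lec_ev = _evidence_pair(normalized, approach)
    return hard_segment(
        threshold_map(mec_ev, threshold),
        threshold_map(lec_ev, threshold),
        tie_rule=tie_rule,
        approach=approach,
        level="participant",
        participant_id=subject.participant_id,
    )


def variability_map(segmentations: list[SegmentationLabelMap]) -> VariabilityMap:
    """Count, per voxel, how many participants called it MEC and LEC."""
    if not segmentations:
        raise InputError("variability_map needs at least one segmentation")
    first = segmentations[0]
    for s in segmentations[1:]:
        if not s.grid.same_grid(first.grid):
            raise AlignmentError("segmentations do not share a grid")
    mec = np.sum([s.label_indicator(MEC) for s in segmentations], axis=0)
    lec = np.sum([s.label_indicator(LEC) for s in segmentations], axis=0)
    return VariabilityMap(
        mec_counts=first.grid.with_data(mec.astype(np.int32)),
        lec_counts=first.grid.with_data(lec.astype(np.int32)),
        n_participants=len(segmentations),
    )


def segment_group(
    group_maps: dict[str, GroupMap],
    approach: str,
    kernel_mm: float = DEFAULT_KERNEL_MM,
    threshold: float = DEFAULT_THRESHOLD,
    tie_rule: str = "background",
) -> SegmentationLabelMap:
    """Group-level pipeline: (combine,) smooth, threshold, hard-segment.

    ``kernel_mm = 0`` disables smoothing (the limit case), otherwise each
    evidence map is Gaussian-smoothed before thresholding.  When the group
    maps carry an EC mask, the smoothing halo that spills beyond the EC is
    clipped back to the mask so labels stay inside the EC.
    """
    mec_ev, lec_ev = _evidence_pair(group_maps, approach)
    if kernel_mm > 0:

        def _smooth_clip(ev):
            ev = smooth_gaussian(ev, kernel_mm)
            if ev.ec_mask is not None:
                ev = ev.with_data(ev.grid.data * ev.ec_mask.indicator)
            return ev

        mec_ev, lec_ev = _smooth_clip(mec_ev), _smooth_clip(lec_ev)
    return hard_segment(
        threshold_map(mec_ev, threshold),
        threshold_map(lec_ev, threshold),
        tie_rule=tie_rule,
        approach=approach,
        level="group",
    )
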