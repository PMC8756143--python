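"""Border-orientation and size quantification of MEC/LEC segmentations.

The orientation of the MEC-LEC border is summarized by the vector between the
centers of gravity (CoG) of the two labels, computed per hemisphere in world
millimetres.  The acute angle between that vector and the posterior-anterior
(PA) or medial-lateral (ML) axis is mapped linearly to a percentage: 0° means
the border is 100% oriented along that axis, 90° means 0%.  Hemispheres are
summarized as mean ± mean absolute deviation (MAD); for two values a, b the
MAD about their mean is |a − b| / 2.

Note the convention: the percentage is named after the axis the *CoG vector*
aligns with, so a pure PA gradient (border plane orthogonal to PA) scores
%PA = 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSegmentationError, ParameterError
from .grids import AxisFrame
from .segmentation import LEC, MEC, SegmentationLabelMap

__all__ = [
    "HemisphereOrientation",
    "BorderOrientationResult",
    "SizeReport",
    "center_of_gravity",
    "axis_angle",
    "angle_to_percentage",
    "border_orientation",
    "size_report",
    "two_value_mad",
]

_LABEL_NAMES = {MEC: "MEC", LEC: "LEC"}


def two_value_mad(a: float, b: float) -> float:
    """Mean absolute deviation about the mean of two values: |a − b| / 2."""
    return abs(a - b) / 2.0


@dataclass(frozen=True)
class HemisphereOrientation:
    """One hemisphere's CoG geometry and derived orientation numbers."""

    hemisphere: str
    cog_mec: np.ndarray  # world mm
    cog_lec: np.ndarray
    cog_vector: np.ndarray  # MEC -> LEC
    angle_pa: float  # degrees in [0, 90]
    angle_ml: float
    pct_pa: float  # percent in [0, 100]
    pct_ml: float


@dataclass(frozen=True)
class BorderOrientationResult:
    """Per-hemisphere orientation plus across-hemisphere mean ± MAD summary.

    ``summary`` maps each of ``angle_pa``, ``angle_ml``, ``pct_pa``,
    ``pct_ml`` to a ``(mean, mad)`` pair; it is ``None`` when only one
    hemisphere was analyzed.
    """

    hemispheres: dict  # "left"/"right" -> HemisphereOrientation
    summary: dict | None


@dataclass(frozen=True)
class SizeReport:
    """Label voxel counts (both hemispheres combined) and their ratio."""

    mec_voxels: int
    lec_voxels: int
    ratio: float | None  # MEC / LEC; None when LEC is empty
    approach: str
    voxel_size_mm: tuple[float, float, float]


def center_of_gravity(
    labelmap: SegmentationLabelMap,
    label: int,
    hemisphere: str = "both",
    frame: AxisFrame | None = None,
) -> np.ndarray:
    """Unweighted mean world-mm coordinate of the voxel centers with ``label``."""
    frame = frame or AxisFrame()
    selector = labelmap.label_indicator(label)
    if hemisphere != "both":
        selector = selector & frame.hemisphere_selectors(labelmap.grid)[hemisphere]
    if not selector.any():
        name = _LABEL_NAMES.get(label, str(label))
        raise DegenerateSegmentationError(
            f"label {name} is empty in hemisphere {hemisphere!r}"
        )
    return labelmap.grid.world_coordinates()[selector].mean(axis=0)


def axis_angle(v: np.ndarray, axis: np.ndarray) -> float:
    """Acute angle (degrees, [0, 90]) between a vector and an axis.

    Uses |v · axis|, making the result independent of the vector's sign —
    the MEC→LEC direction is a labeling convention, not an orientation.
    """
    v = np.asarray(v, dtype=float)
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise DegenerateSegmentationError("zero-length CoG vector")
    cosine = abs(np.dot(v, axis)) / (norm * np.linalg.norm(axis))
    return math.degrees(math.acos(min(1.0, cosine)))


def angle_to_percentage(angle_deg: float) -> float:
    """Map an angle in [0°, 90°] linearly to an orientation percentage.

    0° → 100% (fully oriented along the axis), 90° → 0% (orthogonal).
    """
    if not 0 <= angle_deg <= 90:
        raise ParameterError(f"angle must be in [0, 90] degrees, got {angle_deg}")
    return (1.0 - angle_deg / 90.0) * 100.0


def border_orientation(
    labelmap: SegmentationLabelMap,
    frame: AxisFrame | None = None,
    hemispheres: tuple[str, ...] = ("left", "right"),
) -> BorderOrientationResult:
    """CoG-vector border orientation per hemisphere, with mean ± MAD summary.

    Requires both MEC and LEC nonempty in every requested hemisphere.  Pass a
    single-element ``hemispheres`` for one-sided analysis; the summary is
    then omitted.
    """
    frame = frame or AxisFrame()
    per_hemi: dict[str, HemisphereOrientation] = {}
    for hemi in hemispheres:
        cog_mec = center_of_gravity(labelmap, MEC, hemi, frame)
        cog_lec = center_of_gravity(labelmap, LEC, hemi, frame)
        vec = cog_lec - cog_mec
        angle_pa = axis_angle(vec, frame.pa_axis)
        angle_ml = axis_angle(vec, frame.ml_axis(hemi))
        per_hemi[hemi] = HemisphereOrientation(
            hemisphere=hemi,
            cog_mec=cog_mec,
            cog_lec=cog_lec,
            cog_vector=vec,
            angle_pa=angle_pa,
            angle_ml=angle_ml,
            pct_pa=angle_to_percentage(angle_pa),
            pct_ml=angle_to_percentage(angle_ml),
        )
    summary = None
    if len(per_hemi) == 2:
        summary = {}
        for key in ("angle_pa", "angle_ml", "pct_pa", "pct_ml"):
            a, b = (getattr(per_hemi[h], key) for h in ("left", "right"))
            summary[key] = ((a + b) / 2.0, two_value_mad(a, b))
    return BorderOrientationResult(hemispheres=per_hemi, summary=summary)


def size_report(labelmap: SegmentationLabelMap) -> SizeReport:
    """MEC and LEC voxel counts over both hemispheres, and their ratio."""
    mec = int(labelmap.label_indicator(MEC).sum())
    lec = int(labelmap.label_indicator(LEC).sum())
    return SizeReport(
        mec_voxels=mec,
        lec_voxels=lec,
        ratio=(mec / lec) if lec > 0 else None,
        approach=labelmap.approach,
        voxel_size_mm=tuple(labelmap.grid.voxel_size),
    )
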