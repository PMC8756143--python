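"""Exception hierarchy for the EC segmentation pipeline.

All pipeline errors derive from :class:`EcSegError` so callers can catch the
whole family; each subclass also derives from the closest builtin so that
generic handling (``except ValueError``) keeps working.
"""


class EcSegError(Exception):
    """Base class for all errors raised by ecconnseg."""


class FormatError(EcSegError, ValueError):
    """A file could not be parsed as the expected format."""


class DimensionalityError(EcSegError, ValueError):
    """A volume does not have exactly three spatial dimensions."""


class BoundsError(EcSegError, IndexError):
    """A voxel index lies outside the volume."""


class EmptyMaskError(EcSegError, ValueError):
    """An operation required a nonempty mask."""


class GeometryError(EcSegError, ValueError):
    """Requested geometry does not fit the grid or is degenerate."""


class ParameterError(EcSegError, ValueError):
    """A numeric parameter is outside its valid range."""


class AlignmentError(EcSegError, ValueError):
    """Volumes expected to share a grid do not."""


class DegenerateMapError(EcSegError, ValueError):
    """A connectivity map is unusable (e.g. all-zero hemisphere)."""


class DegenerateSegmentationError(EcSegError, ValueError):
    """A segmentation lacks the labels an operation requires."""


class InputError(EcSegError, ValueError):
    """Required inputs (seed maps, segmentations) are missing."""
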