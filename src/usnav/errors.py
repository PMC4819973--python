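"""Exception hierarchy for the usnav toolkit.

All domain errors derive from :class:`UsnavError` so callers (and the CLI)
can distinguish bad input from programming errors.
"""


class UsnavError(Exception):
    """Base class for all usnav domain errors."""


class FrameMismatchError(UsnavError):
    """Coordinate-frame labels do not chain (e.g. composing tracker->sensor
    with image->sensor). Raised instead of warning: a silent frame mix-up is
    exactly the calibration-chain bug frame labels exist to prevent."""


class ExtrapolationError(UsnavError):
    """A pose was requested outside the recorded time range of a stream."""


class InsufficientLandmarksError(UsnavError):
    """Fewer than three common landmark names between the two sets."""


class DegenerateGeometryError(UsnavError):
    """Landmarks are collinear (or otherwise rank-deficient) so the rotation
    is not uniquely determined."""


class NoCorrespondenceError(UsnavError):
    """ICP found no usable correspondences (empty overlap, or every candidate
    rejected by the orientation gate)."""


class EmptyInputError(UsnavError):
    """An operation received no usable data (no unmasked pixels, empty
    volume, empty error budget, ...)."""


class EmptySegmentationError(UsnavError):
    """Thresholding left no voxels above threshold."""


class FormatError(UsnavError):
    """A file did not conform to its documented format."""
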