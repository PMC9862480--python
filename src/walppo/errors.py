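"""Exception hierarchy.

Validation problems (bad parameters, malformed inputs) and I/O problems are
kept distinct so the command-line layer can map them to different exit codes.
"""


class WalppoError(Exception):
    """Base class for all package errors."""


class ValidationError(WalppoError, ValueError):
    """Invalid parameter or input value."""


class GeometryError(ValidationError):
    """Phantom geometry cannot be realised (e.g. grid too small)."""


class SegmentationError(WalppoError):
    """Lung segmentation failed (no candidate lung component)."""


class DegenerateDataError(WalppoError):
    """A statistic is undefined on this input (e.g. all paired differences zero)."""


class UndefinedStatisticError(DegenerateDataError):
    """A correlation/agreement index is undefined (e.g. zero variance)."""


class WalppoIOError(WalppoError, OSError):
    """File-level failure (missing path, unreadable volume)."""


class MissingFileError(WalppoIOError):
    pass


class FormatError(WalppoIOError):
    """File exists but does not hold the expected content (e.g. non-3D NIfTI)."""


class ShapeMismatchError(ValidationError):
    """CT volume and lobe label map shapes disagree."""


class UnknownLabelError(ValidationError):
    """Lobe label map contains labels outside {0..5}."""
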