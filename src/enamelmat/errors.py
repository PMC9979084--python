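"""Exception hierarchy for the enamelmat pipeline.

Every stage raises a subclass of :class:`EnamelmatError` so callers can
distinguish pipeline failures from programming errors; most are also
``ValueError`` subclasses because they signal invalid inputs.
"""


class EnamelmatError(Exception):
    """Base class for all enamelmat errors."""


class ValidationError(EnamelmatError, ValueError):
    """An input violates a documented precondition or invariant."""


class CalibrationError(ValidationError):
    """Density calibration pairs are degenerate (no unique line)."""


class EmptySegmentationError(EnamelmatError):
    """Thresholding produced no enamel candidates, or cleaning removed all."""


class OrientationAmbiguousError(EnamelmatError):
    """The mask's inertia tensor has no well-separated principal axis."""


class EmptyProfileError(EnamelmatError):
    """No axial slice survived the minimum-area filter."""


class EmptyBandError(EnamelmatError):
    """A requested axial band contains no profile samples."""


class AlignmentError(EnamelmatError):
    """Profiles to be averaged have disjoint axial ranges."""


class VolumeBudgetError(EnamelmatError):
    """A phantom render would exceed the configured voxel budget."""


class EstimabilityError(EnamelmatError):
    """ANOVA with interaction requested on a design with empty cells."""


class FormatError(EnamelmatError):
    """A volume file is unreadable or lacks required metadata."""


class UndefinedSurfaceError(EnamelmatError):
    """Fluorescein surface region has zero intensity; no reference."""
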