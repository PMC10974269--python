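"""Exception hierarchy for the b2bsync pipeline.

Every stage raises a subclass of :class:`B2BError`, so callers (and the CLI)
can catch one base class and turn any pipeline failure into a diagnostic.
"""


class B2BError(Exception):
    """Base class for all b2bsync errors."""


class InvalidChannelSetError(B2BError):
    """Empty channel list or duplicate channel labels."""


class InvalidWindowError(B2BError):
    """Window geometry is unusable (odd / non-positive sample count)."""


class BandRangeError(B2BError):
    """A frequency band falls outside the axis range or yields no bins."""


class FilterSpecError(B2BError):
    """Filter parameters are inconsistent with the sampling rate."""


class TooShortError(B2BError):
    """A sample sequence is too short for the requested operation."""


class MissingChannelError(B2BError):
    """A required channel label is absent from a window or frame."""


class AlignmentError(B2BError):
    """Two frames/windows that must share a window index do not."""


class ShapeError(B2BError):
    """Matrix shapes do not agree."""


class NoCalibrationError(B2BError):
    """Calibration baseline requested from zero windows."""


class InsufficientCalibrationError(B2BError):
    """The session ended before the configured calibration completed."""


class DesyncError(B2BError):
    """The two subject streams produced mismatched window indices."""


class ParseError(B2BError):
    """A recording file does not match the raw CSV schema."""


class InsufficientDataError(B2BError):
    """A statistical test was given an empty sample."""


class IncompleteDyadError(B2BError):
    """A dyad is missing one of the two task series."""


class ValidationError(B2BError):
    """A synthetic-data specification is internally inconsistent."""
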