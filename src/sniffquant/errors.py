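"""Exception hierarchy for the sniffquant pipeline.

Each pipeline stage raises a distinct subclass of :class:`SniffQuantError`
so callers (and the CLI, which maps them to exit codes) can tell a bad
configuration from a tracking failure from a degenerate signal.
"""


class SniffQuantError(Exception):
    """Base class for all sniffquant errors."""


class InvalidParameterError(SniffQuantError, ValueError):
    """A parameter violates its documented domain (e.g. non-positive period)."""


class GeometryError(SniffQuantError):
    """A synthetic dome excursion would leave the image bounds."""


class FormatError(SniffQuantError):
    """Input frames are malformed (mixed dimensions, unreadable file...)."""


class TrackingError(SniffQuantError):
    """Dome tracking failed (too many frames without a usable edge)."""


class FitError(SniffQuantError):
    """Model fitting failed on all attempts; carries optimizer diagnostics."""


class ExtrapolationError(SniffQuantError):
    """A prediction grid extends beyond the allowed extrapolation window."""


class DegenerateSignalError(SniffQuantError):
    """The series has no dominant oscillation to fit a sinusoid to."""


class NoMotionError(SniffQuantError):
    """No extrema with the required prominence were found."""


class MatchingError(SniffQuantError):
    """No extremum of one side could be paired with the other side."""


class UnstableEstimateError(SniffQuantError):
    """Extremum matching failed in too many posterior draws."""
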