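"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`PlanarGaitError` so callers (and the
CLI) can distinguish bad configuration from bad data from degenerate geometry.
"""


class PlanarGaitError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PlanarGaitError):
    """Malformed input file (bad header, unknown dialect)."""


class ValidationError(PlanarGaitError):
    """Structurally valid file whose contents violate an invariant."""


class GeometryError(PlanarGaitError):
    """Degenerate camera/scene geometry (point behind camera, Z <= 0, ...)."""


class CalibrationError(PlanarGaitError):
    """Front-camera stature calibration is impossible (degenerate span)."""


class NumericalError(PlanarGaitError):
    """Iterative numeric routine failed to converge."""


class EventDetectionError(PlanarGaitError):
    """Gait events could not be detected (too few crossings, no stance...)."""


class DirectionError(EventDetectionError):
    """Walking direction is ambiguous (net hip displacement too small)."""


class InsufficientDataError(PlanarGaitError):
    """Not enough valid frames/rows for the requested computation."""


class StatisticsError(PlanarGaitError):
    """Agreement statistic undefined for this input (zero variance, ...)."""


class ConfigError(PlanarGaitError):
    """Invalid configuration value."""
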