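"""Exception hierarchy shared across the package."""


class MotionPrfError(Exception):
    """Base class for all package errors."""


class ConfigError(MotionPrfError, ValueError):
    """Unknown or malformed configuration key."""


class ValidationError(MotionPrfError, ValueError):
    """A parameter violates its documented constraints."""


class GeometryError(MotionPrfError, ValueError):
    """Array shapes or grids do not match."""


class ResolutionError(MotionPrfError, ValueError):
    """The pixel grid is too coarse to represent the requested geometry."""


class DegenerateSeriesError(MotionPrfError, ValueError):
    """A time series has zero variance where variance is required."""


class NoFitError(MotionPrfError, RuntimeError):
    """No usable model prediction was available for fitting."""


class InsufficientDataError(MotionPrfError, ValueError):
    """Too few observations for the requested statistic."""
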