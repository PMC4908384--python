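"""Exception types shared across the package."""


class OptocochleaError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(OptocochleaError, ValueError):
    """A physical or numerical parameter is out of its admissible range."""


class ResolutionError(OptocochleaError, ValueError):
    """A grid is too coarse to resolve the requested feature."""


class GridError(OptocochleaError, ValueError):
    """A time or space grid violates a structural requirement (e.g. uniformity)."""


class MeasurementRangeError(OptocochleaError, ValueError):
    """A value lies outside the measurement range (e.g. zero transmission)."""


class InsufficientDataError(OptocochleaError, ValueError):
    """Not enough usable data points for a fit."""


class ConfigError(OptocochleaError, ValueError):
    """A configuration file or mapping is missing or malformed."""


class NumericError(OptocochleaError, RuntimeError):
    """An iterative numerical procedure failed to converge."""
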