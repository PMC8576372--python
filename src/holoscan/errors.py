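"""Exception taxonomy shared across the package."""


class HoloscanError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(HoloscanError, ValueError):
    """A physical or numerical parameter is out of its valid domain."""


class StructuralError(HoloscanError, ValueError):
    """Array shapes / lattices are mutually inconsistent."""


class GeometryError(HoloscanError, ValueError):
    """A placement or extent does not fit the hosting grid."""


class ConfigError(HoloscanError, ValueError):
    """Configuration entries are missing, inconsistent or out of range."""


class NumericalFailureError(HoloscanError, RuntimeError):
    """An iterative computation produced non-finite values."""


class UndefinedCorrelationError(HoloscanError, ValueError):
    """A correlation statistic was requested on zero-variance data."""
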