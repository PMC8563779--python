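"""Exception hierarchy shared across the package."""


class ShapeChainError(Exception):
    """Base class for all package errors."""


class ProfileParseError(ShapeChainError):
    """Malformed coordinate file (bad row, mixed dimensionality, too few points)."""


class ConfigurationError(ShapeChainError):
    """Inconsistent or infeasible user settings (piece length, portion counts...)."""


class HomologyError(ShapeChainError):
    """Correspondence violated: unequal M-segment piece counts, point-count
    mismatches between a segment and its portion, bad segment matrices."""


class DegeneracyError(ShapeChainError):
    """Numerically degenerate input (coincident points, zero-length chords)."""


class DimensionError(ShapeChainError, TypeError):
    """Operation requested in the wrong ambient dimension (e.g. torsion in 2D)."""


class CollinearityError(ShapeChainError):
    """Singular pooled covariance in discriminant analysis."""


class DependencyError(ShapeChainError):
    """A pipeline stage was invoked before its upstream artifact exists."""
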