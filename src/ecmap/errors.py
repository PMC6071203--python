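"""Exception hierarchy shared across the package."""


class EcmapError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(EcmapError):
    """Invalid or inconsistent configuration."""


class GridTooSmallError(ConfigError):
    """The voxel grid cannot accommodate the requested network layout."""


class DataError(EcmapError):
    """Malformed or out-of-range input data."""


class SchemaError(DataError):
    """A tabular input is missing required columns or has duplicates."""


class GridMismatchError(DataError):
    """Images do not share a common voxel grid."""


class EmptyDataError(DataError):
    """No usable voxels remain after quality screening."""


class DimensionError(DataError):
    """Array shapes are incompatible with the requested operation."""


class ZeroVarianceError(DataError):
    """A quantity with no variance was passed to a variance-based test."""


class CollinearityError(DataError):
    """A design or map set is rank deficient."""


class DesignError(DataError):
    """Task events are inconsistent with the run timing."""


class ConvergenceError(EcmapError):
    """An iterative solver failed to converge within its budget."""


class ReducibleGraphError(EcmapError):
    """The correlation graph decomposes into disconnected components,
    so the leading eigenvector is not uniquely defined."""
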