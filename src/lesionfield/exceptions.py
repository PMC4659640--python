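"""Exception hierarchy shared across the pipeline.

``SchemaError`` subclasses map to CLI exit code 2 (malformed or
inconsistent inputs); ``NumericalError`` subclasses map to exit code 3
(a computation that is undefined for the given values).
"""


class LesionfieldError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(LesionfieldError):
    """Input data violates a structural contract (shape, counts, labels)."""


class CoordinateError(SchemaError):
    """Perimetry point coordinates disagree between grids that must match."""


class GridError(SchemaError):
    """3-D volumes that must share a voxel grid do not."""


class SpaceError(SchemaError):
    """A volume is tagged with the wrong coordinate space for an operation."""


class ConfigurationError(LesionfieldError):
    """An option value outside its documented domain."""


class NumericalError(LesionfieldError):
    """A quantity is mathematically undefined for the supplied values."""


class UndefinedChangeError(NumericalError):
    """Relative change requested against a zero baseline."""


class PairingError(LesionfieldError):
    """Two classification runs cannot be paired split-by-split."""
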