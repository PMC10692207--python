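"""Exception hierarchy used across the package.

Every error that a pipeline stage can raise derives from :class:`SleepsigError`
so callers can catch package failures with a single except clause while still
getting a specific type (and message naming the offending column, voxel,
region, ...) for programmatic handling.
"""


class SleepsigError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(SleepsigError, ValueError):
    """An argument violates a documented precondition."""


class SingularDesignError(SleepsigError):
    """A regression design matrix is rank deficient.

    The message names the first column that is (numerically) collinear with
    the columns preceding it.
    """


class UndefinedCorrelationError(SleepsigError):
    """A correlation is requested between vectors with zero variance."""


class InsufficientSampleError(SleepsigError):
    """Too few observations for the requested statistic."""


class DesignOverflowError(SleepsigError):
    """The hemodynamic shift pushes a task block past the end of the run."""


class DegenerateVoxelError(SleepsigError):
    """A voxel has a (near-)zero run mean, so percent signal change is undefined."""


class InvalidLabelsError(SleepsigError):
    """Classification labels do not contain both classes."""


class IncompleteDesignError(SleepsigError):
    """One or more stimulus categories are absent from a run."""


class DegenerateSeriesError(SleepsigError):
    """A region time series has zero variance."""


class InvalidDiagonalError(SleepsigError):
    """A connectivity matrix has a non-positive diagonal entry."""


class InvalidMatrixError(SleepsigError):
    """A matrix violates a structural requirement (e.g. symmetry)."""


class AtlasIncompleteError(SleepsigError):
    """The atlas lacks centroids or network labels required by an operation."""


class StratificationError(SleepsigError):
    """A cohort stratum is empty or too small to fit the models."""


class SchemaError(SleepsigError):
    """A table read from disk does not match the expected schema."""


class ParseError(SleepsigError):
    """A file could not be parsed; the message names the offending line."""


class DependencyError(SleepsigError):
    """A pipeline stage requires the output of a stage that is disabled."""
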