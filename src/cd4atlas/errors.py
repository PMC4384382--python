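"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: configuration/validation problems -> 2,
data/annotation problems -> 3, numerical failures -> 4.
"""


class AtlasError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 1


class ConfigError(AtlasError):
    """Invalid configuration value; message names the offending field."""

    exit_code = 2


class ValidationError(ConfigError):
    """Invalid argument to an operation (thresholds, fractions, p-values)."""


class DataError(AtlasError):
    """Malformed or inconsistent input data."""

    exit_code = 3


class AnnotationError(DataError):
    """Missing or invalid gene/isoform annotation; message names the record."""


class ConsistencyError(DataError):
    """Objects passed together were not produced from the same configuration."""


class IncompleteInputError(DataError):
    """A required slice of the input (pair, replicate, subtype) is missing."""


class NumericalError(AtlasError):
    """A numerical procedure failed to produce a usable result."""

    exit_code = 4


class NormalizationError(NumericalError):
    """No usable reference genes for size-factor estimation."""


class InsufficientDataError(NumericalError):
    """Too few observations for a fit."""


class FitError(NumericalError):
    """Degenerate model fit (e.g. collapsed mixture variance)."""
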