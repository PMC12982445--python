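"""Exception hierarchy shared across the pipeline."""


class LifespanDError(Exception):
    """Base class for all package-specific errors."""


class DomainError(LifespanDError, ValueError):
    """An argument lies outside the mathematically valid domain."""


class DegenerateVarianceError(DomainError):
    """Both standard deviations are zero: the effect size is undefined."""


class InsufficientSampleError(DomainError):
    """A per-group count is too small for the requested statistic."""


class UnusableRowError(LifespanDError, ValueError):
    """A chart row lacks the fields needed to extract (mean, SD)."""


class UnsupportedDialectError(UnusableRowError):
    """A chart row uses a percentile layout the normality back-calculation
    cannot handle (e.g. ranks not symmetric about 50)."""


class ExtrapolationError(DomainError):
    """An age lies outside a regression specification's valid range."""


class InvalidSpecError(LifespanDError, ValueError):
    """A regression/growth specification violates its own invariants."""


class SchemaError(LifespanDError, ValueError):
    """An input table is missing required columns or cannot be decoded."""


class EmptyInputError(LifespanDError, ValueError):
    """An operation received no usable data."""


class ParameterError(LifespanDError, ValueError):
    """A tuning parameter (window width, step, ...) is invalid."""


class UnknownMetricError(LifespanDError, KeyError):
    """A metric name does not resolve to a subject-record field."""


class SensitivityUndefinedError(LifespanDError, ValueError):
    """Leave-one-dataset-out needs at least two distinct datasets."""


class ConfigurationError(LifespanDError, ValueError):
    """A simulation model or config document is internally inconsistent."""
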