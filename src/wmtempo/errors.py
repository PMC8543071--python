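"""Exception hierarchy shared across the pipeline."""


class WmTempoError(Exception):
    """Base class for all package errors."""


class InvalidInputError(WmTempoError, ValueError):
    """A scalar/array argument is outside its documented domain."""


class ConfigurationError(WmTempoError, ValueError):
    """A design or generation configuration violates its invariants."""


class SchemaError(WmTempoError, ValueError):
    """A trial table is missing required columns or has malformed values."""


class ParseError(WmTempoError, ValueError):
    """A cohort file could not be parsed; carries row/column context."""


class MissingResponseError(WmTempoError, ValueError):
    """A per-trial operation was asked for a trial without a report."""


class IncompleteDesignError(WmTempoError, ValueError):
    """A participant x cell matrix has holes where completeness is required."""


class InsufficientDataError(WmTempoError, ValueError):
    """Too few trials / participants for the requested estimate."""


class DegenerateVarianceError(WmTempoError, ValueError):
    """A test statistic is undefined because the variance is zero."""
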