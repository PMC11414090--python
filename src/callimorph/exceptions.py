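"""Package-wide exception types."""


class CallimorphError(Exception):
    """Base class for all package errors."""


class SchemaError(CallimorphError):
    """Input table is missing mandatory columns or has a malformed header."""


class ValidationError(CallimorphError):
    """Input violates a data invariant (duplicate ids, bad codes, ...)."""


class DegenerateDataError(CallimorphError):
    """A statistic is undefined for the given data (zero variance, n < 2)."""


class SaturationError(CallimorphError):
    """A pairwise genetic distance is undefined (log argument <= 0)."""


class ConvergenceError(CallimorphError):
    """An iterative estimator failed to converge."""
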