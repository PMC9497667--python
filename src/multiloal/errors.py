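"""Exception hierarchy shared across the package."""


class MultiloalError(Exception):
    """Base class for all package errors."""


class ParseError(MultiloalError):
    """A file does not conform to one of the TSV dialects."""


class ValidationError(MultiloalError):
    """An in-memory object violates a structural invariant."""


class ParameterError(MultiloalError, ValueError):
    """A numeric parameter is out of range or infeasible."""


class UsageError(MultiloalError):
    """Inputs are individually valid but mutually inconsistent."""


class UndefinedMetricError(MultiloalError):
    """A quality metric is undefined for the given inputs (e.g. empty truth)."""
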