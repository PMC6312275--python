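"""Exception types raised by clonecast."""


class ClonecastError(Exception):
    """Base class for all package errors."""


class SchemaError(ClonecastError):
    """A column or attribute does not resolve against the cohort schema."""


class CohortParseError(ClonecastError):
    """A cell value violates its attribute's type or range."""


class MissingValueError(ClonecastError):
    """A required value is missing and cannot be resolved."""


class NotFittedError(ClonecastError):
    """A preprocessor or model was used before being fitted."""


class ConvergenceError(ClonecastError):
    """Coordinate descent failed to converge within the iteration budget."""

    def __init__(self, message, l1_ratio=None, lam=None):
        super().__init__(message)
        self.l1_ratio = l1_ratio
        self.lam = lam


class TriageError(ClonecastError):
    """Triage statistic undefined (needs at least one patient per DCB class)."""


class ConfigError(ClonecastError):
    """A configuration object is internally inconsistent or infeasible."""
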