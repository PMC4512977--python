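"""Exception hierarchy shared across the package."""


class EelvKitError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(EelvKitError):
    """The input table is missing required columns or has an invalid layout."""


class ParseError(EelvKitError):
    """A cell could not be parsed; carries row/column context in the message."""


class DomainError(EelvKitError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class ConfigError(EelvKitError, ValueError):
    """A configuration object has one or more invalid fields."""


class ConvergenceError(EelvKitError):
    """An iterative estimator failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace if trace is not None else []


class DegenerateDataError(EelvKitError, ValueError):
    """The data are degenerate for the requested statistic (single class,
    empty after exclusion, zero variance, ...)."""
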