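"""Exception hierarchy for the GAW analysis pipeline."""


class GawvotError(Exception):
    """Base class for all package errors."""


class InputError(GawvotError):
    """Malformed or empty input data."""


class ConfigError(GawvotError):
    """Invalid configuration value (filter band, kernel size, fractions...)."""


class ParseError(InputError):
    """A data file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class DegenerateSignalError(InputError):
    """Signal carries no usable oscillation (all zero, constant...)."""


class EstimationError(GawvotError):
    """A signal-derived quantity (f0, ...) could not be estimated."""


class InsufficientDataError(GawvotError):
    """Too few peaks / samples for the requested operation."""


class ParameterError(GawvotError):
    """Model parameters outside their valid region."""


class FitError(GawvotError):
    """Curve fitting failed structurally (rank-deficient design, ...)."""
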