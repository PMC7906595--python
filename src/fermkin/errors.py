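"""Exception hierarchy shared across the package."""


class FermkinError(Exception):
    """Base class for all package-specific errors."""


class DomainError(FermkinError, ValueError):
    """An argument lies outside its physical domain (e.g. negative concentration)."""


class ConfigError(FermkinError, ValueError):
    """Invalid configuration: unknown inhibition family, bad grid, unknown key."""


class ValidationError(FermkinError, ValueError):
    """Structurally invalid input data (empty table, length mismatch, bad record)."""


class ParseError(ValidationError):
    """A delimited-text file could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class FitError(FermkinError, RuntimeError):
    """A regression or nonlinear fit could not be carried out."""


class SelectionError(FitError):
    """Model selection impossible: no candidate fit converged."""


class NumericalError(FermkinError, ArithmeticError):
    """Non-finite state encountered during integration."""


class UndefinedStatisticError(FermkinError, ValueError):
    """A statistic is undefined for the given data (e.g. zero-variance R^2)."""
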