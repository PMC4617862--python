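"""Exception types shared across the package."""


class VpaPkPdError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(VpaPkPdError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateKineticsError(VpaPkPdError, ValueError):
    """Absorption and elimination rate constants coincide (ka == ke)."""


class UndefinedResponseError(VpaPkPdError, ValueError):
    """Responder status cannot be evaluated (zero baseline seizure frequency)."""


class TableValidationError(VpaPkPdError, ValueError):
    """A patient table failed schema validation.

    Carries the offending row (1-based, excluding header) and column when known.
    """

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        suffix = f" ({', '.join(loc)})" if loc else ""
        super().__init__(message + suffix)
        self.row = row
        self.column = column


class InvalidComparisonError(VpaPkPdError, ValueError):
    """Two fits being compared were not produced from the same records."""


class NumericalError(VpaPkPdError, ArithmeticError):
    """A non-finite intermediate value was encountered during estimation."""
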