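"""Exception hierarchy shared across the package."""


class SoilRiskError(Exception):
    """Base class for package errors."""


class SchemaError(SoilRiskError):
    """Input table is missing required columns or has an unusable layout."""


class ValidationError(SoilRiskError):
    """One or more rows violate a record invariant.

    Carries the offending row numbers (1-based, counting the header as
    line 1) so callers can report them.
    """

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


class DomainError(SoilRiskError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class CapabilityError(SoilRiskError):
    """A required toxicity constant (RfD or SF) is absent for an element."""


class FittingError(SoilRiskError):
    """Distribution fitting cannot proceed (too few or degenerate data)."""
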