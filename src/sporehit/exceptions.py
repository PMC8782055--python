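"""Exception hierarchy shared across the pipeline.

Every validation failure raises a subclass of :class:`SporehitError` so CLI
entry points can map any domain error to a one-line diagnostic and a
non-zero exit status.
"""


class SporehitError(Exception):
    """Base class for all domain errors."""


class InvalidInputError(SporehitError, ValueError):
    """An argument violates a documented precondition."""


class InvalidWindowError(InvalidInputError):
    """Energy-transfer or spectral window with lo >= hi."""


class InsufficientDataError(SporehitError, ValueError):
    """Too few points (or too few distinct doses) to fit."""


class NonIdentifiableError(SporehitError, ValueError):
    """The data carry no information about the parameter (e.g. flat survival)."""


class FitFailureError(SporehitError, RuntimeError):
    """Optimizer failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InvalidModelError(SporehitError, ValueError):
    """Operation applied to a fit with the wrong event count k."""


class MissingModeError(SporehitError, ValueError):
    """A required spectral mode is absent from a fitted peak list."""


class CoverageError(SporehitError, ValueError):
    """Requested band or cut range not covered by the wavenumber grid."""


class DegenerateRatioError(SporehitError, ZeroDivisionError):
    """Denominator band area is zero."""


class SchemaError(SporehitError, ValueError):
    """Tabular input is missing or mistypes a required column."""


class ParseError(SporehitError, ValueError):
    """Malformed spectrum file; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number
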