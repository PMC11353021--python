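"""Exception hierarchy.

Dose-tracking sits in a safety context, so malformed input fails loudly
with a specific error type rather than being silently coerced.
"""


class CedlarError(Exception):
    """Base class for all package errors."""


class SchemaError(CedlarError):
    """A required column or field is missing from tabular input."""


class RecordValidationError(CedlarError):
    """A single input row violates a record-level invariant.

    Carries the 1-based data-row number when raised during CSV parsing.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class FixtureInconsistencyError(CedlarError):
    """A packaged reference table is internally inconsistent."""


class EmptyHistoryError(CedlarError):
    """A patient history carries no irradiating (non nuclear-medicine) events."""


class UndefinedIntervalError(CedlarError):
    """Average study interval requested for a history with fewer than two exams."""


class UndefinedRateError(CedlarError):
    """Recurrence rate requested over a period containing no CT studies."""


class OutOfSchemeError(CedlarError):
    """Patient age falls outside the age-band scheme."""


class UnknownProtocolError(CedlarError):
    """CT protocol absent from a coefficient table."""


class MissingDatumError(CedlarError):
    """A required per-exam quantity (e.g. DLP) is absent."""


class SexMismatchError(CedlarError):
    """Sex-specific organs from both sexes mixed in one dose vector."""


class MissingWeightError(CedlarError):
    """An organ present in a dose vector has no tissue weighting factor."""


class MissingCoefficientError(CedlarError):
    """No risk coefficient grid for the requested (sex, cancer site)."""


class ConventionError(CedlarError):
    """Unrecognised dose-scaling convention identifier."""


class UnsupportedOracleError(CedlarError):
    """Simulation config has no closed-form exceedance probability."""
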