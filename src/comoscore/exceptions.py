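"""Exception hierarchy for comoscore.

All package errors derive from :class:`ComoscoreError` so callers can catch
one base class; the CLI maps validation errors to exit code 2 and
model/calibration errors to exit code 3.
"""


class ComoscoreError(Exception):
    """Base class for all comoscore errors."""


class ValidationError(ComoscoreError):
    """Invalid input data or arguments (CLI exit code 2)."""


class MalformedCodeError(ValidationError):
    """An ICD-10 diagnosis code that cannot be normalized."""


class EmptyCohortError(ValidationError):
    """No episodes survived reading or filtering."""


class MapIntegrityError(ComoscoreError):
    """A packaged comorbidity map violates its structural invariants."""


class DegenerateStrataError(ValidationError):
    """Too few distinct score values to form quartile strata."""


class UndefinedStatisticError(ValidationError):
    """A correlation/agreement statistic is undefined (zero variance)."""


class SeparationError(ComoscoreError):
    """Logistic fit shows complete or quasi-complete separation (exit code 3)."""


class CalibrationError(ComoscoreError):
    """The synthetic generator cannot reach the requested target (exit 3)."""
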