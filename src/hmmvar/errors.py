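"""Exception hierarchy.

All package errors derive from :class:`HmmvarError` so callers can catch one
base class at pipeline boundaries.
"""


class HmmvarError(Exception):
    """Base class for all hmmvar errors."""


class FormatError(HmmvarError):
    """A file violates its documented layout.

    Carries the 1-based line number where parsing failed when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ValidationError(HmmvarError):
    """An in-memory object violates its invariants."""


class EmissionLookupError(HmmvarError, LookupError):
    """Match-state index out of range or residue outside the 20-letter alphabet."""


class DuplicateHitError(FormatError):
    """Two hit rows describe the same (protein, model, envelope)."""


class ConsistencyError(HmmvarError):
    """An internal bookkeeping invariant was broken (e.g. count below zero)."""


class UndefinedMetricError(HmmvarError):
    """A performance metric has a zero denominator; names the metric."""

    def __init__(self, metric: str, reason: str = "zero denominator"):
        super().__init__(f"metric '{metric}' is undefined: {reason}")
        self.metric = metric


class SingleClassError(HmmvarError):
    """ROC / threshold calibration needs both a positive and a negative class."""
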