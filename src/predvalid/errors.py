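"""Typed exceptions shared across the package.

Resampling loops distinguish recoverable per-replicate failures
(:class:`FittingError`) from contract violations (everything else), so the
skip-and-count policy can catch narrowly.
"""


class PredvalidError(Exception):
    """Base class for all package errors."""


class DataError(PredvalidError):
    """Input data violates the Dataset contract (missing values, bad outcome)."""


class DegenerateOutcomeError(DataError):
    """Outcome has a single class; discrimination/calibration undefined."""


class FittingError(PredvalidError):
    """Logistic fit failed (separation or non-convergence).

    Carries ``context`` describing where the failure happened (e.g. which
    resampling strategy / replicate), so callers can log-and-skip.
    """

    def __init__(self, message: str, context: str | None = None):
        self.context = context
        super().__init__(message if context is None else f"{message} [{context}]")


class ValidationDesignError(PredvalidError):
    """A validation strategy was configured in a way that cannot be run."""


class InsufficientDataError(PredvalidError):
    """Too few individuals or events for the requested computation."""
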