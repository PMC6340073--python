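"""Exception hierarchy for the lipi package."""


class LipiError(Exception):
    """Base class for all package errors."""


class SchemaError(LipiError):
    """A required column or field is missing or malformed."""


class ValidationError(LipiError):
    """Data violates a structural invariant (duplicate keys, out-of-range values)."""


class DegenerateDataError(LipiError):
    """An input is degenerate for the requested computation (single class, all ties)."""


class CalibrationError(LipiError):
    """The outcome-model intercept cannot be calibrated to the target prevalence."""


class NonConvergenceError(LipiError):
    """A regression fit failed to converge (e.g. separation)."""

    def __init__(self, message: str, feature: str | None = None):
        super().__init__(message)
        self.feature = feature


class UndefinedEstimateError(LipiError):
    """A requested estimate is undefined for the given counts (zero cells)."""


class TieError(LipiError):
    """Point assignment is ambiguous because effect magnitudes tie at a rank boundary."""


class ScoringError(LipiError):
    """A patient cannot be scored (missing features)."""


class EvaluationError(LipiError):
    """Model evaluation failed for every requested row."""
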