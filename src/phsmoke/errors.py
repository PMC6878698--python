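"""Exception hierarchy for the phsmoke pipeline."""


class PhsmokeError(Exception):
    """Base class for all package errors."""


class ValidationError(PhsmokeError):
    """Invalid input data or configuration (bad level, bad marginal, bad range)."""


class TaxLookupError(PhsmokeError):
    """A record's state is missing from the excise-tax table."""


class FittingError(PhsmokeError):
    """Logistic fit failed: separation, non-convergence, or rank deficiency."""


class PredictionError(PhsmokeError):
    """Prediction requested for a record with levels unknown to the model."""


class CalibrationError(PhsmokeError):
    """Threshold calibration could not reach the target prevalence."""


class StateError(PhsmokeError):
    """Operation requested before the object is in the required state."""
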