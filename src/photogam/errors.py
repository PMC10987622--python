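"""Exception hierarchy for photogam."""


class PhotogamError(Exception):
    """Base class for all photogam errors."""


class ScheduleError(PhotogamError):
    """Invalid illumination schedule definition or query."""


class SchemaError(PhotogamError):
    """Input table is missing required columns or has the wrong shape."""


class DataValidationError(PhotogamError):
    """Input table contains invalid values (negative distances, duplicates...)."""


class DesignError(PhotogamError):
    """Model specification cannot be turned into a valid design matrix."""


class FitError(PhotogamError):
    """Model fitting failed (rank deficiency, non-convergence)."""


class PredictionError(PhotogamError):
    """Prediction requested outside the fitted covariate range or levels."""


class InferenceError(PhotogamError):
    """Post-hoc inference contract violated (no data, zero denominator...)."""


class ConfigError(PhotogamError):
    """Run configuration is inconsistent or incomplete."""
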