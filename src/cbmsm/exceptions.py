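"""Exception hierarchy for cbmsm."""


class CbmsmError(Exception):
    """Base class for all package errors."""


class SchemaError(CbmsmError):
    """A column-role mapping is missing or inconsistent with the data file."""


class DataError(CbmsmError):
    """Malformed input data (duplicates, bad types)."""


class PanelValidationError(CbmsmError):
    """Panel violates a structural invariant (e.g. non-monotone dropout)."""


class SpecTermError(CbmsmError):
    """A model/restriction term references an unavailable column or lag."""


class FittingError(CbmsmError):
    """A process-model fit failed (separation, non-convergence)."""


class DegenerateDataError(CbmsmError):
    """Data carry no information for the requested fit (constant response)."""


class PositivityError(CbmsmError):
    """A fitted probability hit 0/1 at machine tolerance for some person-period."""


class RankError(CbmsmError):
    """A design or restriction matrix is rank deficient where full rank is required."""


class ConfigError(CbmsmError):
    """Invalid or internally inconsistent run configuration."""


class CalibrationError(CbmsmError):
    """Calibration solver failed (infeasible targets, no convergence)."""
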