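"""Exception hierarchy for the MR pipeline."""


class MRError(Exception):
    """Base class for all package errors."""


class ConfigError(MRError):
    """Invalid configuration (column map, scenario, pipeline config)."""


class DataError(MRError):
    """Invalid or inconsistent input data (e.g. duplicate variant ids)."""


class InsufficientInstrumentsError(MRError):
    """Too few instruments for the requested estimator."""


class UndefinedRatioError(MRError):
    """Wald ratio requested for a variant with zero exposure effect."""


class IdentifiabilityError(MRError):
    """Rank-deficient design: collinear exposures or constant regressor."""


class ConvergenceError(MRError):
    """Numerical optimisation failed to converge within the restart budget."""
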