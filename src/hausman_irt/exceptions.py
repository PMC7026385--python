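"""Exception hierarchy for estimation and testing failures."""


class HausmanIRTError(Exception):
    """Base class for package errors."""


class ConfigurationError(HausmanIRTError):
    """Invalid configuration value (quadrature size, strategy, preset name)."""


class DataError(HausmanIRTError):
    """Data unusable for estimation (degenerate items, margins at 0/1)."""


class ConvergenceError(HausmanIRTError):
    """Optimizer failed to converge and the caller requested strict mode."""


class InfeasibleTestError(HausmanIRTError):
    """The Hausman statistic is undefined (trace of the difference covariance
    is not positive)."""


class BootstrapUnstableError(HausmanIRTError):
    """Too many bootstrap replicates failed to fit."""


class ScenarioUnstableError(HausmanIRTError):
    """Too many scenario replications failed."""
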