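"""Exception hierarchy."""


class PwdbError(Exception):
    """Base class for all package errors."""


class ConfigError(PwdbError):
    """Malformed or incomplete configuration input."""


class TopologyError(ConfigError):
    """Network graph is not a valid rooted arterial tree."""


class DomainError(PwdbError, ValueError):
    """Argument outside the mathematical/physiological domain of an operation."""


class ParameterError(PwdbError, ValueError):
    """Mutually infeasible or nonphysical parameter combination."""


class CalibrationError(PwdbError):
    """Optimizer failed to fit model constants to targets."""

    def __init__(self, msg, residuals=None):
        super().__init__(msg)
        self.residuals = residuals


class SolverError(PwdbError):
    """Numerical failure (blowup, CFL violation, Newton non-convergence)."""

    def __init__(self, msg, diagnostics=None):
        super().__init__(msg)
        self.diagnostics = diagnostics or {}


class DegenerateSignalError(PwdbError, ValueError):
    """Signal carries no usable pulsatile information (flat/constant/empty)."""
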