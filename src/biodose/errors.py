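"""Exception hierarchy for biodose."""


class BiodoseError(Exception):
    """Base class for all package-specific errors."""


class DomainError(BiodoseError, ValueError):
    """An argument lies outside its mathematical domain."""


class ConfigurationError(BiodoseError, ValueError):
    """A model, prior or grid specification is invalid."""


class BelowBackgroundError(DomainError):
    """Observed dicentric frequency is below the calibration background."""


class InfeasibleInputError(DomainError):
    """No non-negative dose solves the yield equation."""


class ConvergenceError(BiodoseError, RuntimeError):
    """An iterative scheme failed to converge; carries the trajectory."""

    def __init__(self, message, trajectory=None):
        super().__init__(message)
        self.trajectory = list(trajectory) if trajectory is not None else []


class DegeneratePosteriorError(BiodoseError, RuntimeError):
    """Prior mass is numerically zero against the likelihood support."""


class UndefinedCurvatureError(BiodoseError, RuntimeError):
    """Log-posterior curvature at the mode is not negative definite."""
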