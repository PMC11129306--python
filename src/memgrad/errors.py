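"""Exception and warning types used across memgrad."""


class MemgradError(Exception):
    """Base class for all memgrad errors."""


class ValidationError(MemgradError, ValueError):
    """Invalid input values or inconsistent parameters."""


class SizingError(ValidationError):
    """A requested geometry does not fit in the available box."""


class FitError(MemgradError, RuntimeError):
    """A model fit could not be performed (too few points, degenerate data)."""


class FitConvergenceError(FitError):
    """A nonlinear fit or self-consistent iteration failed to converge.

    Carries diagnostic information instead of returning silent defaults.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class AccuracyWarning(UserWarning):
    """The requested parameters are within contract but degrade accuracy."""
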