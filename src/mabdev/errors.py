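"""Exception types shared across the package."""


class MabdevError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(MabdevError, ValueError):
    """Raised when an input violates a precondition (bad grid, empty data...)."""


class ScanDomainError(MabdevError, ValueError):
    """Raised when a requested quantity lies outside the measured scan window."""


class NoSignalError(MabdevError, ValueError):
    """Raised when a trace contains no detectable transition or peak."""


class FitConvergenceError(MabdevError, RuntimeError):
    """Raised when a nonlinear fit fails; carries the best attempt so far."""

    def __init__(self, message, best=None, residual=None):
        super().__init__(message)
        self.best = best
        self.residual = residual
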