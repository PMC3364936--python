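"""Exception hierarchy for porefep."""


class PorefepError(Exception):
    """Base class for all porefep errors."""


class ValidationError(PorefepError, ValueError):
    """Raised when an input violates a documented precondition."""


class DomainError(PorefepError, ValueError):
    """Raised when a numeric argument is outside its physical domain."""


class ConvergenceError(PorefepError, RuntimeError):
    """Raised when an iterative solver fails to converge.

    Carries the last bracket examined, when available, in ``bracket``.
    """

    def __init__(self, message, bracket=None):
        super().__init__(message)
        self.bracket = bracket


class DesignError(PorefepError, RuntimeError):
    """Raised when restraint design cannot locate the required features.

    ``profile`` holds the free-energy profile that was examined, for
    diagnostics.
    """

    def __init__(self, message, profile=None):
        super().__init__(message)
        self.profile = profile


class MissingAtomsError(PorefepError, KeyError):
    """Raised when required atoms are absent from a structure."""


class FitError(PorefepError, RuntimeError):
    """Raised when model fitting is impossible on the supplied data."""
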