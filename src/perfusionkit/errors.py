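"""Exception hierarchy shared by all pipeline stages."""


class PerfusionKitError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PerfusionKitError, ValueError):
    """A physical quantity or array violates a precondition."""


class ConfigError(PerfusionKitError, ValueError):
    """A configuration value or key is not accepted."""


class ParseError(PerfusionKitError, ValueError):
    """An input file could not be parsed; the message names the offending row."""


class NumericalError(PerfusionKitError, RuntimeError):
    """An iterative solver failed to reach its tolerance.

    Attributes
    ----------
    residual : float or None
        Relative residual at the point of failure, when available.
    """

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class StateError(PerfusionKitError, RuntimeError):
    """An operation was called on an object in an unusable state."""


class InsufficientObjectsError(PerfusionKitError, ValueError):
    """Fewer detected objects than the statistic requires."""


class PackingError(PerfusionKitError, RuntimeError):
    """Synthetic object placement failed after bounded retries."""
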