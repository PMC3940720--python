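"""Exception hierarchy shared across the package."""


class Kv13TcellError(Exception):
    """Base class for all package-specific errors."""


class DomainError(Kv13TcellError, ValueError):
    """An argument is outside the physically meaningful domain."""


class ConfigurationError(Kv13TcellError, ValueError):
    """A scheme/protocol/config document is structurally invalid."""


class NumericalError(Kv13TcellError, RuntimeError):
    """A numerical routine failed (singular system, no convergence, ...)."""


class FitError(NumericalError):
    """A least-squares fit failed to converge.

    Carries the last iterate so callers can inspect how far the
    optimizer got before giving up.
    """

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate
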