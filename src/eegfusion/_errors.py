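"""Exception hierarchy shared across the package."""


class EEGFusionError(Exception):
    """Base class for all package errors."""


class InvalidInputError(EEGFusionError, ValueError):
    """Raised when data handed to an operation violates its contract."""


class ConfigurationError(EEGFusionError, ValueError):
    """Raised when a configuration object is internally inconsistent."""


class NumericalError(EEGFusionError, ArithmeticError):
    """Raised when a computation produces non-finite values."""
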