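"""Exception types shared across the package."""


class SigforgeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SigforgeError, ValueError):
    """A configuration value is missing, malformed or out of range."""


class ValidationError(SigforgeError, ValueError):
    """An input table or matrix violates its schema."""


class EstimationError(SigforgeError, RuntimeError):
    """A statistical estimate could not be computed from the given data."""
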