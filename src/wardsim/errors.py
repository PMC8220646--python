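"""Exception types shared across the package."""


class WardsimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(WardsimError):
    """A configuration value is missing, malformed or out of range."""


class InputError(WardsimError, ValueError):
    """Runtime data handed to an operation violates its preconditions."""


class LogicError(WardsimError, RuntimeError):
    """An internal invariant was violated; indicates a bug, not bad input."""
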