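"""Exception hierarchy shared by all pipeline stages."""


class CardioFuseError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CardioFuseError, ValueError):
    """Raised when data handed to an operation violates its preconditions."""


class ConfigurationError(CardioFuseError, ValueError):
    """Raised for invalid parameter values (kernel sizes, population sizes, specs)."""


class StateError(CardioFuseError, RuntimeError):
    """Raised when an operation is called on an object in the wrong state
    (e.g. predicting with an untrained model)."""
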