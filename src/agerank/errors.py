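"""Exception types shared across the package."""


class AgerankError(Exception):
    """Base class for all package errors."""


class ConfigError(AgerankError, ValueError):
    """A configuration object or file is invalid; the message names the field."""


class ValidationError(AgerankError, ValueError):
    """An input table or argument violates a documented precondition."""
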