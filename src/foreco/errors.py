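"""Exception types shared across the package."""


class ForecoError(Exception):
    """Base class for package errors."""


class ConfigError(ForecoError):
    """A configuration value is invalid; the message names the field."""


class DataError(ForecoError):
    """Input data violate a precondition (empty plot, zero basal area, ...)."""


class ConsistencyError(ForecoError):
    """Two inputs that must come from the same generation run do not match."""
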