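"""Exception types shared across the package."""


class HabsegError(Exception):
    """Base class for package errors."""


class ConfigError(HabsegError, ValueError):
    """A configuration value is invalid; the message names the field."""


class DataError(HabsegError, ValueError):
    """Input data violate the transect-record schema or an operation's domain."""


class FitError(HabsegError, RuntimeError):
    """A model fit could not be completed (e.g. rank deficiency)."""
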