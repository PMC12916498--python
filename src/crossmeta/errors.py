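"""Exception hierarchy."""


class CrossmetaError(Exception):
    """Base class for package errors."""


class ConfigError(CrossmetaError):
    """Invalid configuration (simulation or pipeline)."""


class FormatError(CrossmetaError):
    """Malformed or inconsistent input data."""


class UsageError(CrossmetaError):
    """An operation was called with arguments that violate its contract."""
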