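class DRANetError(Exception):
    """Base class for package errors."""


class InvalidInputError(DRANetError, ValueError):
    """Raised when an input array violates an operation precondition."""


class ConfigurationError(DRANetError, ValueError):
    """Raised when a configuration value is inconsistent with the data."""
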