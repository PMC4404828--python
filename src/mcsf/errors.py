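"""Exception hierarchy shared across the pipeline."""


class McsfError(Exception):
    """Base class for all package errors."""


class ConfigError(McsfError):
    """A configuration file is malformed or violates an invariant."""


class FormatError(ConfigError):
    """A configuration file could not be parsed at all."""


class DataError(McsfError):
    """An input data file violates its contract (bad rows, bad timestamps)."""


class UsageError(McsfError):
    """An operation was called with inconsistent arguments."""


class DegenerateInputError(McsfError):
    """Too little usable data to compute the requested quantity."""
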