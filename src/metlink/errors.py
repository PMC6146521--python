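"""Exception hierarchy shared by all metlink stages.

The CLI maps these onto exit codes: DataError -> 1, UsageError and
ConfigError -> 2.  Everything else is a bug and propagates.
"""


class MetlinkError(Exception):
    """Base class for all metlink errors."""


class DataError(MetlinkError):
    """Malformed or inconsistent input data (bad record, missing field)."""


class UsageError(MetlinkError):
    """The caller asked for something contractually invalid."""


class ConfigError(UsageError):
    """A configuration object failed validation."""


class NormalizationError(DataError):
    """Size-factor normalization is undefined for the given matrix."""
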