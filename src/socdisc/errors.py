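"""Exception hierarchy shared across the pipeline stages."""


class SocdiscError(Exception):
    """Base class for all package errors."""


class ConfigError(SocdiscError):
    """Invalid configuration; the message names the offending field."""


class DataError(SocdiscError):
    """Malformed or out-of-contract input data."""


class UsageError(SocdiscError):
    """An operation was called outside its contract."""


class FitError(SocdiscError):
    """Model fitting failed to converge; carries diagnostics in the message."""


class StatisticError(SocdiscError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class ModelError(SocdiscError):
    """A regression model cannot be estimated (e.g. rank deficiency)."""
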