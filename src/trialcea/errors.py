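"""Exception hierarchy.

``DataError`` covers malformed or inconsistent input data (CLI exit code 1);
``ConfigError`` covers invalid parameters and configuration (exit code 2).
"""


class TrialCeaError(Exception):
    """Base class for all package errors."""


class DataError(TrialCeaError):
    """Malformed or inconsistent input data."""


class ConfigError(TrialCeaError):
    """Invalid parameter or configuration value."""


class BaselineMissingError(DataError):
    """A patient has no baseline observation; LOCF has no origin and the
    patient cannot enter the intention-to-treat analysis."""


class IncompleteTrajectoryError(DataError):
    """An operation that requires a fully imputed trajectory was given one
    with missing follow-up values."""
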