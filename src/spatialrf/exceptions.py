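"""Exception hierarchy.

``ConfigurationError`` covers bad user-supplied settings (flags, fractions,
hyper-parameters); ``DataError`` covers malformed or inconsistent inputs;
``FormatError`` covers unreadable files; ``DegenerateDataError`` flags inputs
on which a statistic is undefined (e.g. zero-variance fields).
"""


class SpatialRFError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SpatialRFError, ValueError):
    """A setting or option is invalid or inconsistent."""


class DataError(SpatialRFError, ValueError):
    """Input data violate a contract (duplicates, misalignment, missing values)."""


class FormatError(DataError):
    """A file could not be parsed in its declared format."""


class DegenerateDataError(DataError):
    """Input is valid but the requested quantity is undefined on it."""
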