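"""Exception hierarchy.

``ConfigError`` covers malformed configuration (CLI exit code 2);
``DataError`` covers problems in the data itself (CLI exit code 3).
"""


class EntrocellError(Exception):
    """Base class for all package errors."""


class ConfigError(EntrocellError):
    """Invalid configuration or parameter values."""


class DataError(EntrocellError):
    """Malformed or inconsistent input data."""


class EmptyResultError(DataError):
    """An operation removed every row/column (e.g. QC filtered all cells)."""
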