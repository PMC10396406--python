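"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigurationError -> 2, DataError -> 3.
"""


class BimrError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BimrError):
    """Invalid configuration: missing columns, bad parameter combinations."""


class DataError(BimrError):
    """Invalid data content: duplicate IDs, missing fields, malformed rows."""


class ParseError(DataError):
    """A row of an input table could not be parsed; message cites the row."""


class DomainError(BimrError, ValueError):
    """An argument is outside the mathematical domain of an operation."""
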