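"""Exception hierarchy.

ConfigurationError covers bad invocations (missing columns, unknown chains,
out-of-range domains); DataError covers unusable input content. The CLI maps
them to distinct exit codes.
"""


class MissenseMapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MissenseMapError):
    """An invocation problem: missing mandatory column, unknown chain, ..."""


class DataError(MissenseMapError):
    """Input content that cannot be used (malformed file, bad bounds, ...)."""


class DomainFileError(DataError):
    """A malformed line in a domain-boundary file; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number
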