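"""Exception hierarchy.

All library errors derive from :class:`ParatagError` so callers (notably
the CLI) can distinguish validation failures from genuine bugs.
"""


class ParatagError(Exception):
    """Base class for all errors raised by this package."""


class OffsetError(ParatagError):
    """A character span points outside the document it is anchored to."""


class ParseError(ParatagError):
    """A serialised file (standoff, CoNLL, OBO) is malformed."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class IntegrityError(ParatagError):
    """Parsed data is syntactically valid but internally inconsistent."""


class ConsistencyError(ParatagError):
    """A label sequence violates the IOBES/ID well-formedness rules."""


class DegenerateSpanError(ParatagError):
    """A span covers no token at all (e.g. whitespace only)."""


class ParameterError(ParatagError):
    """A parameter value is outside its documented domain."""


class ConfigurationError(ParatagError):
    """An unknown strategy or otherwise invalid configuration value."""
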