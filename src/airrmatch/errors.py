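"""Exception hierarchy for airrmatch.

All errors raised deliberately by the library derive from
:class:`AirrMatchError`, so callers (and the command-line wrapper) can
distinguish validated input problems from genuine bugs.
"""


class AirrMatchError(Exception):
    """Base class for all airrmatch errors."""


class FormatError(AirrMatchError):
    """A file-level problem: missing mandatory column, unreadable header."""


class RecordError(AirrMatchError):
    """A record-level problem, reported with the offending 1-based line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


class ParameterError(AirrMatchError):
    """An argument outside its documented domain."""


class OptionError(AirrMatchError):
    """A combination of options that the tool does not support."""
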