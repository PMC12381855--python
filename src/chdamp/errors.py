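"""Exception hierarchy shared across the toolkit.

The CLI maps these onto exit codes: :class:`InputError` -> 1 (user error),
:class:`DataError` and subclasses -> 2 (data error).
"""


class ChdampError(Exception):
    """Base class for all toolkit errors."""


class InputError(ChdampError):
    """Bad user input: missing files, malformed configuration, unknown options."""


class DataError(ChdampError):
    """Inconsistent or unusable data encountered while processing valid inputs."""


class ParseError(DataError):
    """A structure or energy file failed to parse; carries file/line context."""

    def __init__(self, message: str, path=None, line: int | None = None):
        ctx = ""
        if path is not None:
            ctx += f" [{path}"
            if line is not None:
                ctx += f", line {line}"
            ctx += "]"
        super().__init__(message + ctx)
        self.path = path
        self.line = line


class IncompleteCalculationError(DataError):
    """An engine output contains no usable final energy."""
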