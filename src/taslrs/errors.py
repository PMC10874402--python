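"""Exception hierarchy shared by every stage.

The CLI maps :class:`ValidationError` (and subclasses) to exit code 1 and
I/O failures to exit code 2; library users catch :class:`TaslrsError`.
"""


class TaslrsError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(TaslrsError, ValueError):
    """Invalid argument, record, or configuration value."""


class ParseError(ValidationError):
    """A text input could not be parsed; carries file and line context."""

    def __init__(self, message: str, path=None, line: int | None = None):
        ctx = ""
        if path is not None:
            ctx += f"{path}"
        if line is not None:
            ctx += f":{line}"
        super().__init__(f"{ctx}: {message}" if ctx else message)
        self.path = path
        self.line = line
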