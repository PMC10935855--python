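"""Exception hierarchy shared across the package."""


class CladescanError(Exception):
    """Base class for all package-specific errors."""


class InputError(CladescanError, ValueError):
    """A caller supplied an argument that violates an operation's contract."""


class FormatError(CladescanError, ValueError):
    """A file does not conform to its declared format.

    Where possible the message names the offending record and line number.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line
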