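"""Exception hierarchy shared across the package."""


class PrecdaError(Exception):
    """Base class for all precda-specific errors."""


class ParseError(PrecdaError):
    """A malformed cell or row in an input file.

    Carries the 1-based line number (and column, when known) so the
    offending record can be located in the source file.
    """

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        loc = ""
        if line is not None:
            loc = f" (line {line}" + (f", column {column}" if column is not None else "") + ")"
        super().__init__(message + loc)
        self.line = line
        self.column = column


class AmbiguousSynonymError(PrecdaError):
    """The same alias resolves to more than one canonical term."""


class ParameterError(PrecdaError):
    """A parameter outside its documented range."""
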