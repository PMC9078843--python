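"""Exception hierarchy shared across the package."""


class DeltascanError(Exception):
    """Base class for all package errors."""


class CompositionError(DeltascanError, ValueError):
    """Malformed or unresolvable elemental composition string.

    Parameters
    ----------
    message:
        Human-readable description.
    position:
        0-based offset into the source string where parsing failed,
        or ``None`` when not applicable.
    """

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class UnknownElementError(CompositionError):
    """Element symbol absent from the monoisotopic mass table."""

    def __init__(self, symbol: str, position: int | None = None):
        self.symbol = symbol
        super().__init__(f"unknown element {symbol!r}", position)


class TableError(DeltascanError, ValueError):
    """Invalid tabular artifact (missing column, bad value).

    ``line`` is the 1-based line number in the source file (header = 1)
    when the offending row is known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SpecValidationError(DeltascanError, ValueError):
    """A simulation or configuration object violates an invariant.

    Always names the offending field.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")
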