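"""Exception hierarchy shared across the package."""


class XylemtrnError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(XylemtrnError, ValueError):
    """Invalid input data or parameters."""


class MotifParseError(ValidationError):
    """Malformed degenerate-consensus pattern.

    Carries the 1-based column at which parsing failed.
    """

    def __init__(self, message: str, column: int):
        super().__init__(f"{message} (column {column})")
        self.column = column


class PlantingError(ValidationError):
    """A planted element does not fit its promoter window, or overlaps another."""
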