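"""Exception hierarchy shared across the package."""


class Id4ScreenError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(Id4ScreenError, ValueError):
    """Input violates a documented invariant (range, uniqueness, shape...)."""


class ParseError(Id4ScreenError, ValueError):
    """A text input could not be parsed; the message carries coordinates."""


class DegenerateInputError(ValidationError):
    """Statistically degenerate input (constant vector, no events, no split)."""


class UndefinedRatioError(ValidationError):
    """A ratio with a zero denominator was requested."""
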