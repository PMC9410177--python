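"""Exception types shared across the pipeline stages."""


class LignanscreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LignanscreenError):
    """A configuration field is missing or invalid.

    The message always names the offending field.
    """


class ParseError(LignanscreenError):
    """A text input could not be parsed.

    Carries the 1-based line number when the problem is localized.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(LignanscreenError):
    """Input data violates a documented precondition."""
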