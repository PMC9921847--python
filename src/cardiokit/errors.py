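"""Exception hierarchy.

All user-facing failures derive from :class:`CardioKitError` so callers (and
the CLI) can catch one base class.
"""


class CardioKitError(Exception):
    """Base class for all cardiokit errors."""


class ValidationError(CardioKitError):
    """Input data violates a precondition (too short, non-positive, empty...)."""


class ParseError(CardioKitError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigurationError(CardioKitError):
    """A configuration value is inconsistent with the data or with itself."""


class QualityError(CardioKitError):
    """Signal-quality gate failed (e.g. too many rejected beats in a segment)."""

    def __init__(self, message: str, rejection_fraction: float | None = None):
        self.rejection_fraction = rejection_fraction
        super().__init__(message)
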