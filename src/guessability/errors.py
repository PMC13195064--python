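"""Exception hierarchy.

``GuessabilityError`` is the common base; the CLI maps ``ValidationError``
(and subclasses) to exit code 2.
"""


class GuessabilityError(Exception):
    """Base class for all package errors."""


class ValidationError(GuessabilityError):
    """Input data violates a documented invariant."""


class SchemaError(ValidationError):
    """A required column is missing or malformed."""


class ParseError(ValidationError):
    """A cell could not be parsed; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"row {row}: {message}")
        self.row = row


class ReferentialError(ValidationError):
    """A record refers to an unknown concept id."""


class UnknownSegmentError(GuessabilityError):
    """An IPA span could not be matched against the segment inventory."""

    def __init__(self, span: str, context: str = ""):
        msg = f"unknown IPA segment {span!r}"
        if context:
            msg += f" in {context!r}"
        super().__init__(msg)
        self.span = span


class PredictorUnavailableError(GuessabilityError):
    """A predictor needs data (embedding, POS label) the record lacks."""


class ConfigError(GuessabilityError):
    """Inconsistent configuration (feature names, coefficient names...)."""


class ContractError(GuessabilityError):
    """An operation was called with an object violating its contract."""
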