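"""Exception hierarchy for the rechallenge package."""


class RechallengeError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(RechallengeError):
    """A schema definition or an attribute reference is invalid."""


class ValidationError(RechallengeError):
    """A record or cohort does not conform to its schema.

    ``row`` carries the offending 0-based record index when known.
    """

    def __init__(self, message: str, row: int | None = None):
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)
        self.row = row


class ParseError(RechallengeError):
    """A raw value could not be parsed for its declared attribute kind."""


class DegenerateFitError(RechallengeError):
    """Model fitting is impossible on the given data (e.g. an absent class)."""


class UndefinedMetricError(RechallengeError):
    """A performance metric is undefined on the given labels."""


class ModelFormatError(RechallengeError):
    """A serialized model file has an unknown or incompatible format version."""
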