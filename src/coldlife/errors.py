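"""Exception types shared across the package."""


class ColdlifeError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ColdlifeError, ValueError):
    """An argument is outside the domain of the operation."""


class InsufficientDataError(ColdlifeError, ValueError):
    """Too few observations to perform the requested fit or summary."""


class CalibrationError(ColdlifeError, ValueError):
    """Anchor set is missing, inconsistent, or cannot be solved."""


class SchemaError(ColdlifeError, ValueError):
    """A table does not match its expected column schema."""
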