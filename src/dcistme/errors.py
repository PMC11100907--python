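"""Exception and warning types shared across the package."""


class DcisError(Exception):
    """Base class for all package errors."""


class SchemaError(DcisError):
    """A required column is missing or a column cannot be parsed."""


class ValidationError(DcisError):
    """A table or record violates a documented invariant."""


class ConfigError(DcisError):
    """A configuration object is internally inconsistent or out of range."""


class QCWarning(UserWarning):
    """A quantity was computed from too little data, or is undefined.

    Functions that return a missing value (NaN) instead of raising emit this
    warning so callers can surface QC problems without interrupting a cohort
    run.
    """
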