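"""Exception hierarchy shared across the package."""


class PragsubError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PragsubError):
    """A configuration object or file violates its invariants."""


class ValidationError(PragsubError):
    """A declarative input (ruleset, schema) fails validation."""


class SchemaMismatchError(PragsubError):
    """Covariate columns do not match the schema a model was trained on."""

    def __init__(self, missing=(), extra=()):
        self.missing = tuple(missing)
        self.extra = tuple(extra)
        super().__init__(
            f"covariate schema mismatch: missing={list(self.missing)} "
            f"extra={list(self.extra)}"
        )


class UnsupportedInputError(PragsubError):
    """The input is structurally outside an operation's contract."""


class InsufficientDataError(PragsubError):
    """Too few subjects to satisfy an estimator's preconditions."""


class DegenerateInputError(PragsubError):
    """Input is technically valid but yields an undefined statistic."""
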