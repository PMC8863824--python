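"""Exception hierarchy.

Every error carries a short machine-parseable ``category`` used by the CLI
to emit single-line diagnostics (``<category>: <message>``).
"""


class DesiramError(Exception):
    """Base class for all package errors."""

    category = "error"


class BadConfigError(DesiramError):
    """Invalid configuration or arguments (out-of-bounds value, bad group)."""

    category = "bad-config"


class MissingInputError(DesiramError):
    """A required input file or record is absent."""

    category = "missing-input"


class InvalidDataError(DesiramError):
    """Input data violate a structural invariant (non-finite value, bad label)."""

    category = "invalid-data"


class FitError(DesiramError):
    """Template or model fitting failed; carries diagnostics when available."""

    category = "fit-error"

    def __init__(self, message, best_so_far=None, diagnostics=None):
        super().__init__(message)
        self.best_so_far = best_so_far
        self.diagnostics = diagnostics or {}


class SchemaError(DesiramError):
    """Serialised artifact does not match the expected schema."""

    category = "schema-error"
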