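"""Exception hierarchy shared across the package."""


class AddinterError(Exception):
    """Base class for all package errors."""


class ValidationError(AddinterError):
    """Input data violates its declared codebook or schema."""


class FormatError(AddinterError):
    """A file does not have the expected layout (missing columns etc.)."""


class DomainError(AddinterError):
    """A quantity is requested outside its mathematical domain."""


class SingularDesignError(DomainError):
    """Regression design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "singular design matrix; collinear columns: " + ", ".join(self.columns)
        )


class GenerationError(AddinterError):
    """A synthetic-cohort spec cannot be realised."""
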