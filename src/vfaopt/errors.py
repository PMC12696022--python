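"""Exception hierarchy.

Every validation failure raises a distinct, named error so callers (and the
CLI) can report *what* is wrong and *where* (row numbers for tabular input,
term names for singular design matrices).
"""


class VfaoptError(Exception):
    """Base class for all package errors."""


class ValidationError(VfaoptError):
    """Invalid input data or configuration."""


class MissingColumnError(ValidationError):
    """A required column is absent from a tabular source."""


class FieldParseError(ValidationError):
    """A numeric field could not be parsed; message names the row."""


class DuplicateKeyError(ValidationError):
    """Duplicate (treatment, temperature, day, replicate) key; message names the row."""


class DomainError(ValidationError):
    """A value violates its physical domain (negative concentration, alpha outside (0,1), ...)."""


class UnderDeterminedError(VfaoptError):
    """Too few observations to fit the requested polynomial."""


class SingularDesignError(VfaoptError):
    """Design matrix is numerically rank-deficient; message names the offending columns."""
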