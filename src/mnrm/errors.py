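"""Exception hierarchy.

Validation failures raise :class:`ValidationError` subclasses so the CLI can
map them to a dedicated exit code; non-convergence is reported through result
flags, never an exception.
"""


class MNRMError(Exception):
    """Base class for all package errors."""


class ValidationError(MNRMError):
    """Invalid user input: malformed data, configuration, or arguments."""


class DimensionMismatchError(ValidationError):
    """Shapes of latent points, slopes, and scoring vectors disagree."""


class IdentificationError(ValidationError):
    """Scoring functions are linearly dependent (with the constant vector)."""


class CategoryRangeError(ValidationError):
    """A response code lies outside an item's category range."""
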