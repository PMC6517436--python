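"""Exception hierarchy shared across the package."""


class ImiomicsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ImiomicsError, ValueError):
    """An input violates a documented precondition or invariant."""


class GridMismatchError(ValidationError):
    """Two volumes that must share a grid do not."""


class MissingSegmentError(ImiomicsError):
    """A bone segment required for articulated registration has an empty mask."""


class NumericalFailureError(ImiomicsError):
    """An iterative numerical procedure produced non-finite values or failed to converge."""


class FormatError(ImiomicsError):
    """A file on disk could not be parsed into a valid in-memory object."""


class PipelineError(ImiomicsError):
    """A pipeline stage failed; the message names the stage and, where relevant, the subject."""
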