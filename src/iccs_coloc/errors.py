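"""Exception hierarchy shared across the package.

Validation-type errors map to CLI exit code 2; everything else is a
plain failure (exit code 1).
"""


class IccsColocError(Exception):
    """Base class for all package errors."""


class ValidationError(IccsColocError):
    """Invalid argument, config key, or precondition violation."""


class DegenerateInputError(ValidationError):
    """Input is formally valid but analytically degenerate (e.g. constant image)."""


class FormatError(ValidationError):
    """File content does not match the expected layout."""


class SegmentationError(IccsColocError):
    """Nucleus segmentation produced no usable mask."""


class PlacementError(IccsColocError):
    """Rejection sampling could not place objects under the constraints."""
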