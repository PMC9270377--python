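"""Exception hierarchy.

All package errors derive from :class:`SlideAlignError`; most also derive
from a matching builtin so callers can catch either way.
"""


class SlideAlignError(Exception):
    """Base class for all slidealign errors."""


class InvalidInputError(SlideAlignError, ValueError):
    """Malformed or out-of-contract input (wrong shape, empty, mismatched)."""


class DegenerateInputError(SlideAlignError, ValueError):
    """Input that makes the requested estimate ill-posed (zero variance,
    collinear stain vectors, singular transform)."""


class InvalidStateError(SlideAlignError, RuntimeError):
    """Operation requested on an object not yet in the required state
    (e.g. deconvolving with an uncompleted stain matrix)."""


class InsufficientCorrespondencesError(SlideAlignError, RuntimeError):
    """Too few consistent landmark pairs survived matching: the image pair
    is unregistrable under the similarity model."""


class PyramidFormatError(SlideAlignError, ValueError):
    """On-disk pyramid directory is corrupt or inconsistent."""
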