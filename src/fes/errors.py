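"""Exception hierarchy.

Every error raised by this package derives from :class:`FESError`, so callers
(and the CLI) can catch one type.  Subclasses mark *which contract* failed:
sizing, band selection, extrapolation, grid alignment, fingerprint
compatibility, or file parsing.
"""


class FESError(Exception):
    """Base class for all errors raised by the fes package."""


class ValidationError(FESError, ValueError):
    """An input value violates a type invariant or precondition."""


class SizingError(ValidationError):
    """A time series is too short for the requested segmentation."""


class BandError(ValidationError):
    """A frequency band is empty, degenerate, or outside the spectrum."""


class ExtrapolationError(ValidationError):
    """A target frequency lies outside the spectrum's support."""


class AlignmentError(ValidationError):
    """Agent and reference spectra do not cover a common analysis band."""


class CompatibilityError(ValidationError):
    """Two fingerprints (or a fingerprint and a library) cannot be compared."""


class ParseError(FESError, ValueError):
    """A file does not conform to its expected plain-text format."""


class PipelineError(FESError, RuntimeError):
    """An end-to-end pipeline stage failed; the stage name is in the message."""
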