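"""Exception hierarchy for the srcfc toolkit.

Every named failure mode in the pipeline contracts maps onto one of these
classes, so callers can distinguish malformed files (``FormatError``,
``StructuralError``), invalid parameters (``ValidationError``), and
data-driven exclusions (``ExclusionError``, ``InsufficientDataError``).
"""


class SrcFCError(Exception):
    """Base class for all srcfc errors."""


class FormatError(SrcFCError):
    """A file could not be parsed under the declared format."""


class StructuralError(SrcFCError):
    """Parsed content violates a structural contract (shapes, labels, counts)."""


class ValidationError(SrcFCError, ValueError):
    """A parameter or configuration value is outside its documented domain."""


class AlignmentError(StructuralError):
    """Channel/label sets of two objects cannot be reconciled."""


class ExclusionError(SrcFCError):
    """A subject/recording fails an inclusion rule (e.g. too few clean epochs)."""


class InsufficientDataError(SrcFCError):
    """Not enough observations for the requested estimator."""


class ConvergenceError(SrcFCError):
    """An iterative solver failed to converge within its iteration budget."""

    def __init__(self, message, last_delta=None):
        super().__init__(message)
        self.last_delta = last_delta


class EstimationError(SrcFCError):
    """A connectivity estimator is degenerate for the given inputs."""


class ResolutionError(SrcFCError):
    """Spectral resolution too coarse for the requested frequency band."""


class DegenerateScaleError(SrcFCError):
    """A robust scale estimate (MAD) is zero; normalization undefined."""


class NumericalError(SrcFCError):
    """A numerical procedure failed (singular system, diverging series)."""
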