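"""Exception hierarchy shared across the package."""


class OctavaError(Exception):
    """Base class for all octava errors."""


class ValidationError(OctavaError, ValueError):
    """Input violates a documented precondition or invariant."""


class ImageReadError(OctavaError, IOError):
    """File could not be read or decoded as an image."""


class DegenerateImageError(OctavaError):
    """Image cannot be thresholded (e.g. constant intensity)."""


class FAZDetectionError(OctavaError):
    """No avascular candidate survived false-positive filtering."""


class UndefinedZoneError(OctavaError):
    """An ETDRS zone contains no pixels (grid centre too close to border)."""


class InsufficientDataError(OctavaError):
    """Too few samples for the requested model fit or cross-validation."""


class UndefinedCorrelationError(OctavaError):
    """Pearson correlation undefined (constant input vector)."""
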