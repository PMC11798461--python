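"""Exceptions raised by the sphtex pipeline."""


class SphtexError(Exception):
    """Base class for all sphtex errors."""


class LabelNotFoundError(SphtexError, KeyError):
    """Requested label does not occur in the label image."""


class DegenerateObjectError(SphtexError, ValueError):
    """Object mask is empty (or empty after resampling)."""


class CentroidOutsideMaskError(SphtexError, ValueError):
    """Cube-center sample falls outside the segmentation mask.

    The angular projection is only defined for objects whose center is
    foreground; this is a precondition of the whole method.
    """


class ZeroVarianceError(SphtexError, ValueError):
    """Projection is constant, so the texture descriptor is undefined.

    Batch callers may map this case to an all-zero descriptor instead
    (``zero_variance="zero"``).
    """


class BandError(SphtexError, ValueError):
    """Invalid degree/frequency band for band-pass filtering."""
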