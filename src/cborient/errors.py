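"""Exception hierarchy for the cborient package.

Every domain error raised by the measurement pipeline, the preprocessing
steps or the statistics module derives from :class:`CborientError`, so
callers (notably the CLI) can distinguish data problems from bugs.
"""


class CborientError(Exception):
    """Base class for all domain errors raised by cborient."""


# --- image I/O -------------------------------------------------------------

class UnreadableImage(CborientError):
    """The file could not be decoded as a 2D or 3-channel raster."""


class ImageTooSmall(CborientError):
    """Either image dimension is below the 64-pixel minimum."""


class EmptyRecordSet(CborientError):
    """A measurement table was requested for an empty record list."""


class InvalidConfig(CborientError):
    """A configuration document has a bad type, range or unknown key."""


# --- preprocessing ---------------------------------------------------------

class DegenerateImage(CborientError):
    """A constant image cannot be contrast-stretched or transformed."""


class InvalidHueRange(CborientError):
    """An ill-formed circular hue interval was supplied."""


class MaskMismatch(CborientError):
    """Mask dimensions do not match the image they apply to."""


class MaskTooLarge(CborientError):
    """The cellular mask covers (almost) the whole field."""


# --- Fourier pipeline ------------------------------------------------------

class EmptyMask(CborientError):
    """Thresholding/cleanup left no usable spectrum component."""


class MaskTooSmall(CborientError):
    """Fewer than 3 mask pixels: axes cannot be measured."""


class MixedSample(CborientError):
    """Records from more than one sample/technique were averaged."""


# --- reliability statistics ------------------------------------------------

class TooFewSubjects(CborientError):
    """Fewer than 2 subjects (rows): ICC undefined."""


class ZeroVariance(CborientError):
    """Between-subject mean square is zero: ICC undefined."""


class LengthMismatch(CborientError):
    """Paired series of unequal length."""


class TooFewPoints(CborientError):
    """Fewer than 2 paired points for Bland-Altman."""


class ZeroMean(CborientError):
    """Grand mean is not positive: CV undefined for index data."""


class UnpairedSamples(CborientError):
    """A sample is present in one column/rater but not the other."""


class EmptyInput(CborientError):
    """An empty value list was supplied."""


class InvalidParams(CborientError):
    """Synthetic-generator parameters violate their invariants."""
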