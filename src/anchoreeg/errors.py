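"""Exception hierarchy for anchoreeg.

Every error raised by the package derives from :class:`AnchorEEGError`
so callers can catch the whole family with one clause.
"""


class AnchorEEGError(Exception):
    """Base class for all anchoreeg errors."""


class InvalidWindowError(AnchorEEGError, ValueError):
    """A time window with t_end <= t_start or other bad geometry."""


class OutOfRangeError(AnchorEEGError, ValueError):
    """A window or index falls outside the extent of the signal."""


class FormatError(AnchorEEGError, ValueError):
    """A file does not conform to the expected archive layout."""


class ChannelError(AnchorEEGError, KeyError):
    """A requested channel is not present."""


class LabelError(AnchorEEGError, ValueError):
    """An unknown class label."""


class InvalidLengthError(AnchorEEGError, ValueError):
    """A signal or anchor length outside its admissible range."""


class InvalidStrideError(AnchorEEGError, ValueError):
    """A stride incompatible with the anchor or signal length."""


class UnknownAnchorError(AnchorEEGError, ValueError):
    """An anchor length not contained in the anchor set."""


class EmptyBandError(AnchorEEGError, ValueError):
    """A frequency band selecting no spectrogram rows."""


class TooFewRowsError(AnchorEEGError, ValueError):
    """Not enough rows to interpolate along the frequency axis."""


class ZeroGradientError(AnchorEEGError, ValueError):
    """Cost gradient is numerically zero; no perturbation direction exists."""


class EmptyInputError(AnchorEEGError, ValueError):
    """An operation received an empty dataset."""


class ParityError(AnchorEEGError, ValueError):
    """An even number of voters where an odd count is required."""


class InputShapeError(AnchorEEGError, ValueError):
    """An array whose shape does not match the model specification."""


class SpecError(AnchorEEGError, ValueError):
    """An invalid architecture or configuration specification."""


class ConfigError(AnchorEEGError, ValueError):
    """A pipeline configuration that violates the schema.

    The message names the offending field with a dotted path.
    """
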