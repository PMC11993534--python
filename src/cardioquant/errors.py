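"""Exception hierarchy for cardioquant.

All errors raised by the library derive from :class:`CardioQuantError` so
callers (notably the batch pipeline) can capture per-feature failures
without masking programming errors.
"""


class CardioQuantError(Exception):
    """Base class for all cardioquant errors."""


class InputError(CardioQuantError):
    """Unreadable, malformed, or mutually inconsistent inputs."""


class ConfigError(CardioQuantError):
    """Invalid configuration (e.g. channel index out of range)."""


class FormatError(CardioQuantError):
    """A raster with an unsupported layout or dtype."""


class ParameterError(CardioQuantError):
    """An out-of-contract parameter value (negative sigma, even window...)."""


class MissingChannelError(CardioQuantError):
    """An operation needs a stain channel that was not loaded."""


class SegmentationError(CardioQuantError):
    """Segmentation produced no usable objects."""


class InsufficientSampleError(CardioQuantError):
    """Too few objects for the requested statistic."""


class EmptySampleError(InsufficientSampleError):
    """A summary was requested over zero objects."""


class UndefinedOCPError(InsufficientSampleError):
    """No nucleus has a valid directional neighbour; OCP is undefined."""


class DegenerateInputError(CardioQuantError):
    """An input that is formally valid but carries no signal (empty mask)."""


class InsufficientTextureError(DegenerateInputError):
    """Fewer than two co-occurring in-mask pixel pairs."""


class ContractError(CardioQuantError):
    """An internal value violated a documented contract (e.g. GLCM sum != 1)."""


class PlacementError(CardioQuantError):
    """Phantom generation could not place the requested objects."""
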