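"""Exception hierarchy for axoquant.

Every anticipated failure mode raises a subclass of :class:`AxoquantError`,
so callers (the batch runner in particular) can isolate per-image failures
from genuine bugs.
"""


class AxoquantError(Exception):
    """Base class for all axoquant errors."""


class UnsupportedFormatError(AxoquantError):
    """Raised for non-TIFF files or sample formats outside uint8/uint16."""


class UnsupportedLayoutError(AxoquantError):
    """Raised for channel layouts other than single-channel or RGB."""


class EmptyRoiError(AxoquantError):
    """Raised when a mask contains no analyzable (nonzero) pixels."""


class UniformRoiError(AxoquantError):
    """Raised when all in-mask pixels share one intensity.

    A constant ROI has no between-class variance to maximize; this usually
    means a broken export upstream, so it is a hard error rather than a
    silent 0 % measurement. Inspect the control plot for the image.
    """


class EmptyStackError(AxoquantError):
    """Raised for z-stack operations on a stack with no slices."""


class NamingConventionError(AxoquantError):
    """Raised when a filename does not follow ``animalID_brainregion_group[_extra].tif``."""


class EmptyBatchError(AxoquantError):
    """Raised when a batch folder yields zero processable images."""


class SyntheticSpecError(AxoquantError):
    """Raised for infeasible synthetic-fixture specifications."""
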