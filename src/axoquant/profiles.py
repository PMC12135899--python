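"""Axis-projection signal profiles.

For spatial analysis (e.g. innervation across cortical layers) the signal is
projected onto the image axes: per *column* for the x (mediolateral) profile
and per *row* for the y (dorsoventral) profile. Two flavors exist:

* ``binary-count`` — the number of signal pixels in each column/row of a
  binarized image; sums over either axis equal the total signal count.
* ``grayscale-mean`` — the mean in-mask intensity of each column/row, scaled
  to [0, 1] by the bit-depth maximum. Background fluorescence enters this
  one, so its peak-to-baseline contrast is typically lower; the binary
  profile is the one to interpret.

Index 0 is the leftmost column / topmost row of the stored raster; anatomical
alignment (rotating the image so the axes are mediolateral/dorsoventral) is
the user's preprocessing step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .image_io import GrayImage
from .segmentation import BinaryMap, RoiMask

__all__ = [
    "AxisProfile",
    "binary_axis_counts",
    "grayscale_axis_means",
    "normalize_profile",
]


@dataclass
class AxisProfile:
    """Signal distribution along one image axis."""

    axis: str  # "x" (per column) or "y" (per row)
    values: np.ndarray
    kind: str  # "binary-count" or "grayscale-mean"
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.axis not in ("x", "y"):
            raise ValueError("axis must be 'x' or 'y'")
        if self.kind not in ("binary-count", "grayscale-mean"):
            raise ValueError("kind must be 'binary-count' or 'grayscale-mean'")
        self.values = np.asarray(self.values)


def binary_axis_counts(bin_map: BinaryMap, mask: RoiMask) -> tuple[AxisProfile, AxisProfile]:
    """Sum of signal pixels in each column (x) and row (y) of a binary map."""
    if bin_map.signal.shape != mask.shape:
        raise ValueError("binary map and mask dimensions disagree")
    x = bin_map.signal.sum(axis=0).astype(np.int64)
    y = bin_map.signal.sum(axis=1).astype(np.int64)
    return AxisProfile("x", x, "binary-count"), AxisProfile("y", y, "binary-count")


def grayscale_axis_means(img: GrayImage, mask: RoiMask) -> tuple[AxisProfile, AxisProfile]:
    """Mean in-mask intensity per column (x) and row (y), scaled to [0, 1].

    Only pixels inside the mask enter each mean — a whole-column mean would be
    diluted by masked-out zeros. Columns/rows with no in-mask pixels get 0.
    """
    if img.shape != mask.shape:
        raise ValueError("image and mask dimensions disagree")
    px = img.pixels.astype(np.float64)
    m = mask.inside
    scale = float(img.max_value)

    def _means(axis: int) -> np.ndarray:
        counts = m.sum(axis=axis)
        sums = np.where(m, px, 0.0).sum(axis=axis)
        with np.errstate(invalid="ignore"):
            vals = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        return vals / scale

    return (
        AxisProfile("x", _means(0), "grayscale-mean"),
        AxisProfile("y", _means(1), "grayscale-mean"),
    )


def normalize_profile(p: AxisProfile) -> AxisProfile:
    """Divide a profile by its maximum so the peak is exactly 1.

    An all-zero profile cannot be normalized; it is returned unchanged
    (``normalized`` stays False) with a warning.
    """
    vmax = p.values.max() if p.values.size else 0
    if vmax <= 0:
        warnings.warn("all-zero profile cannot be normalized", stacklevel=2)
        return AxisProfile(p.axis, p.values.copy(), p.kind, normalized=False)
    return AxisProfile(p.axis, p.values / vmax, p.kind, normalized=True)
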