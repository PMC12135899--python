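"""Tissue masking, in-mask Otsu thresholding, binarization and quantification.

The analysis domain of a masked-and-cropped ROI is the set of strictly
positive pixels; everything at zero is out-of-tissue padding. The Otsu cut
is computed from the histogram of in-mask pixels only, and percent
innervation is the share of in-mask pixels that land above that cut.

Thresholding convention: *strictly above* — a pixel equal to the threshold
is background. Among cuts with equal between-class variance the lowest is
returned, which makes results deterministic and favors sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyRoiError, UniformRoiError
from .image_io import GrayImage, ImageStack, max_project

__all__ = [
    "RoiMask",
    "ThresholdResult",
    "BinaryMap",
    "RegionMeasurement",
    "derive_mask",
    "otsu_threshold",
    "binarize",
    "quantify_region",
    "stack_global_threshold",
    "stack_quantify",
]


@dataclass
class RoiMask:
    """Boolean map of informative (in-tissue) pixels."""

    inside: np.ndarray

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside, dtype=bool)
        if self.inside.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def n_inside(self) -> int:
        return int(self.inside.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.inside.shape


@dataclass
class ThresholdResult:
    """An Otsu cut plus the class statistics that justify it.

    ``threshold`` is on the image's native intensity scale; signal is
    ``pixel > threshold``. ``class_weights`` are the in-mask fractions at or
    below / above the cut, ``class_means`` their mean intensities, and
    ``between_class_variance`` is w0*w1*(mu0-mu1)^2 at the chosen cut.
    """

    threshold: float
    class_weights: tuple[float, float]
    class_means: tuple[float, float]
    between_class_variance: float


@dataclass
class BinaryMap:
    """{0,1} signal map defined under a mask; zero everywhere outside it."""

    signal: np.ndarray
    mask: RoiMask
    threshold_used: float

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.uint8)
        if self.signal.shape != self.mask.shape:
            raise ValueError("binary map and mask dimensions disagree")

    @property
    def n_signal(self) -> int:
        return int(self.signal.sum())


@dataclass
class RegionMeasurement:
    """One measurement row: percent signal, area and threshold for one sample.

    ``area`` is in um^2 when ``pixel_size_um`` is given, otherwise in pixels
    (``area_units`` says which).
    """

    animal_id: str
    brain_region: str
    group: str
    signal_pct: float
    area: float
    area_units: str
    threshold_used: float
    mask_pixels: int
    pixel_size_um: float | None = None
    filename: str = field(default="")


def derive_mask(img: GrayImage, masked_mode: bool = True) -> RoiMask:
    """Derive the analysis mask from an image.

    In masked mode every strictly positive pixel is in-tissue (no
    morphological cleanup — the zero convention is taken literally). In
    unmasked mode the whole rectangular field is analyzed, zeros included.
    """
    if masked_mode:
        inside = img.pixels > 0
        if not inside.any():
            raise EmptyRoiError(
                "no nonzero pixels: the image has no informative content in masked mode"
            )
        return RoiMask(inside)
    return RoiMask(np.ones(img.shape, dtype=bool))


def _otsu_from_values(values: np.ndarray, bit_depth: int) -> ThresholdResult:
    """Core Otsu search over the intensity values of the in-mask pixels.

    8-bit images use exact integer bins 0..255. 16-bit images use 256 equal
    bins spanning the observed in-mask range; the returned threshold is the
    largest integer strictly below the argmax bin's exclusive upper edge, so
    ``pixel > t`` reproduces the bin split exactly on integer data.
    """
    values = np.asarray(values)
    if values.size < 2:
        raise EmptyRoiError("Otsu needs at least two in-mask pixels")
    vmin = int(values.min())
    vmax = int(values.max())
    if vmin == vmax:
        raise UniformRoiError(
            "all in-mask pixels share one intensity; no threshold separates two "
            "classes — inspect the control plot for this image"
        )

    if bit_depth == 8:
        counts = np.bincount(values.astype(np.int64), minlength=256).astype(np.float64)
        levels = np.arange(256, dtype=np.float64)
        cut_values = levels[:-1]  # cut t: class0 = v <= t, class1 = v > t
    else:
        span = vmax - vmin + 1
        idx = ((values.astype(np.int64) - vmin) * 256) // span  # 0..255
        counts = np.bincount(idx, minlength=256).astype(np.float64)
        sums = np.bincount(idx, weights=values.astype(np.float64), minlength=256)
        # exclusive upper edge of bin k is vmin + (k+1)*span/256; the cut is
        # the largest integer strictly below it
        edges = vmin + (np.arange(1, 256) * span) / 256.0
        cut_values = np.ceil(edges) - 1.0
        levels = None  # per-bin sums carry the exact means

    n = counts.sum()
    cum_counts = np.cumsum(counts)[:-1]
    if bit_depth == 8:
        cum_sums = np.cumsum(counts * levels)[:-1]
        total_sum = (counts * levels).sum()
    else:
        cum_sums = np.cumsum(sums)[:-1]
        total_sum = sums.sum()

    w0 = cum_counts / n
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_sums / cum_counts
        mu1 = (total_sum - cum_sums) / (n - cum_counts)
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[(cum_counts == 0) | (cum_counts == n)] = 0.0

    smax = float(sigma_b.max())
    if smax <= 0.0:
        raise UniformRoiError("between-class variance is zero at every cut")
    # lowest cut attaining the maximum; the relative tolerance keeps exact
    # mathematical ties (plateaus over empty bins) ties under float round-off
    best = int(np.argmax(sigma_b >= smax * (1.0 - 1e-12)))

    t = float(cut_values[best])
    below = values <= t
    n0 = int(below.sum())
    n1 = values.size - n0
    res = ThresholdResult(
        threshold=t if bit_depth == 16 else int(t),
        class_weights=(n0 / values.size, n1 / values.size),
        class_means=(float(values[below].mean()), float(values[~below].mean())),
        between_class_variance=float(sigma_b[best]),
    )
    return res


def otsu_threshold(img: GrayImage, mask: RoiMask) -> ThresholdResult:
    """Otsu threshold over in-mask pixels only.

    Builds a 256-bin histogram of the pixels inside ``mask`` and returns the
    cut maximizing the between-class variance w0*w1*(mu0-mu1)^2, lowest cut
    on ties. Out-of-mask pixels never enter the histogram.
    """
    if img.shape != mask.shape:
        raise ValueError("image and mask dimensions disagree")
    return _otsu_from_values(img.pixels[mask.inside], img.bit_depth)


def binarize(img: GrayImage, mask: RoiMask, th: ThresholdResult) -> BinaryMap:
    """Classify in-mask pixels: strictly above the threshold -> signal (1)."""
    if img.shape != mask.shape:
        raise ValueError("image and mask dimensions disagree")
    signal = (img.pixels > th.threshold) & mask.inside
    return BinaryMap(signal.astype(np.uint8), mask, threshold_used=th.threshold)


def quantify_region(
    bin_map: BinaryMap,
    mask: RoiMask,
    animal_id: str = "",
    brain_region: str = "",
    group: str = "",
    pixel_size_um: float | None = None,
    filename: str = "",
) -> RegionMeasurement:
    """Percent innervation and ROI area for one binarized image.

    P = 100 * signal pixels / in-mask pixels. Area is mask_pixels *
    pixel_size_um^2 when the pixel size is known, else mask_pixels (pixel
    units).
    """
    n_inside = mask.n_inside
    if n_inside == 0:
        raise EmptyRoiError("cannot quantify an empty ROI")
    if pixel_size_um is not None and pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    pct = 100.0 * bin_map.n_signal / n_inside
    if pixel_size_um is not None:
        area, units = n_inside * pixel_size_um**2, "um^2"
    else:
        area, units = float(n_inside), "pixel"
    return RegionMeasurement(
        animal_id=animal_id,
        brain_region=brain_region,
        group=group,
        signal_pct=pct,
        area=area,
        area_units=units,
        threshold_used=bin_map.threshold_used,
        mask_pixels=n_inside,
        pixel_size_um=pixel_size_um,
        filename=filename,
    )


def stack_global_threshold(stack: ImageStack, mask: RoiMask) -> ThresholdResult:
    """Otsu over the pooled in-mask histogram of all slices of a z-stack."""
    if stack.shape != mask.shape:
        raise ValueError("stack and mask dimensions disagree")
    pooled = stack.as_array()[:, mask.inside].ravel()
    return _otsu_from_values(pooled, stack.bit_depth)


def stack_quantify(
    stack: ImageStack,
    mask: RoiMask,
    animal_id: str = "",
    brain_region: str = "",
    group: str = "",
    pixel_size_um: float | None = None,
) -> tuple[list[RegionMeasurement], float, float]:
    """Quantify a z-stack with one global threshold.

    Every slice is binarized with the stack-wide Otsu cut. Returns the
    per-slice measurements, the 3-D percentage (signal voxels over in-mask
    voxels across all slices) and the flat percentage (percent signal of the
    per-pixel maximum of the binarized slices). The flat binary map is
    pixel-identical to binarizing the maximum intensity projection with the
    same threshold, because max commutes with a fixed-cut threshold; the 3-D
    percentage can only be lower than or equal to the flat one.
    """
    th = stack_global_threshold(stack, mask)
    per_slice = []
    binaries = []
    for i, sl in enumerate(stack.slices):
        b = binarize(sl, mask, th)
        binaries.append(b.signal)
        per_slice.append(
            quantify_region(
                b, mask, animal_id, brain_region, group, pixel_size_um,
                filename=f"slice{i:03d}",
            )
        )
    total_signal = int(np.sum([b.sum() for b in binaries]))
    stack_3d_pct = 100.0 * total_signal / (mask.n_inside * stack.n_slices)
    flat = np.maximum.reduce(binaries)
    flat_pct = 100.0 * int(flat.sum()) / mask.n_inside
    # invariant: flat binary == binarize(MIP) under the same threshold
    mip_binary = binarize(max_project(stack), mask, th)
    assert np.array_equal(flat, mip_binary.signal)
    return per_slice, stack_3d_pct, flat_pct
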