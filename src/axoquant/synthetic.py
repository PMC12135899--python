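"""Ground-truthed synthetic ROI images, stacks and acquisition transforms.

The generator emulates the imaging contract the pipeline assumes: an
arbitrary-shaped tissue mask surrounded by exactly-zero padding, a nonzero
background fluorescence floor inside the mask, and bright axon-like strokes
painted as constant-width random walks until a known fraction of in-mask
pixels carries signal. Intensities are Gaussian around the background and
signal means and clamped to [1, max] inside the mask, so no in-tissue pixel
is ever zero.

The default palette — 8-bit, background mean 40, signal mean 200, noise SD
10 — separates the two intensity classes by 16 SD, an unambiguous
signal-to-noise regime in which the Otsu cut must land between the classes.

Every generator is a pure function of its spec (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import SyntheticSpecError
from .image_io import GrayImage, ImageStack
from .segmentation import BinaryMap, RoiMask

__all__ = [
    "SyntheticSpec",
    "SyntheticSample",
    "generate_roi_image",
    "apply_exposure_transform",
    "generate_stack",
    "make_nonfluorescent_pair",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic ROI image."""

    height: int = 128
    width: int = 160
    mask_shape: str = "ellipse"  # "ellipse" | "polygon" | "full"
    background_mean: float = 40.0
    signal_mean: float = 200.0
    noise_sd: float = 10.0
    target_fraction: float = 0.10
    stroke_width: int = 2
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise SyntheticSpecError("image must be at least 8x8")
        if not 0.0 < self.target_fraction < 1.0:
            raise SyntheticSpecError("target_fraction must lie strictly in (0, 1)")
        if self.signal_mean <= self.background_mean:
            raise SyntheticSpecError("signal_mean must exceed background_mean")
        if self.background_mean - self.noise_sd < 1:
            raise SyntheticSpecError(
                "background floor too close to zero: background_mean - noise_sd must be >= 1"
            )
        if self.mask_shape not in ("ellipse", "polygon", "full"):
            raise SyntheticSpecError(f"unknown mask_shape {self.mask_shape!r}")
        if self.stroke_width < 1:
            raise SyntheticSpecError("stroke_width must be >= 1")
        if self.bit_depth not in (8, 16):
            raise SyntheticSpecError("bit_depth must be 8 or 16")


@dataclass
class SyntheticSample:
    """A generated image plus its exact ground truth."""

    image: GrayImage
    truth_mask: RoiMask
    truth_signal: BinaryMap
    achieved_fraction: float


def _make_mask(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height, spec.width
    if spec.mask_shape == "full":
        return np.ones((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    if spec.mask_shape == "ellipse":
        ry, rx = h * 0.42, w * 0.42
        return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    # polygon: a random star-convex blob around the center
    n_vert = 8
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vert))
    radii = rng.uniform(0.55, 0.95, n_vert)
    theta = np.arctan2(yy - cy, xx - cx)
    r = np.hypot((yy - cy) / (h * 0.48), (xx - cx) / (w * 0.48))
    bound = np.interp(theta, angles, radii, period=2 * np.pi)
    return r <= bound


def _paint_strokes(
    mask: np.ndarray, target_pixels: int, stroke_width: int, rng: np.random.Generator
) -> np.ndarray:
    """Paint random-walk strokes inside ``mask`` until exactly ``target_pixels``
    in-mask pixels carry signal (the walk tail is trimmed on overshoot)."""
    h, w = mask.shape
    painted = np.zeros_like(mask)
    inside_idx = np.flatnonzero(mask)
    half = stroke_width // 2
    order: list[tuple[int, int]] = []  # paint order, for exact trimming
    count = 0
    max_strokes = 10_000
    for _ in range(max_strokes):
        if count >= target_pixels:
            break
        start = inside_idx[rng.integers(inside_idx.size)]
        y, x = divmod(int(start), w)
        heading = rng.uniform(0, 2 * np.pi)
        for _step in range(4 * max(h, w)):
            y0, y1 = max(0, y - half), min(h, y + half + 1)
            x0, x1 = max(0, x - half), min(w, x + half + 1)
            for py in range(y0, y1):
                for px in range(x0, x1):
                    if mask[py, px] and not painted[py, px]:
                        painted[py, px] = True
                        order.append((py, px))
                        count += 1
            if count >= target_pixels:
                break
            heading += rng.normal(0, 0.45)
            y += int(round(np.sin(heading)))
            x += int(round(np.cos(heading)))
            if not (0 <= y < h and 0 <= x < w) or not mask[y, x]:
                break  # walked off the tissue; start a new stroke
    if count < target_pixels:
        raise SyntheticSpecError("could not reach the target painted fraction")
    for py, px in order[target_pixels:]:  # trim overshoot from the walk tail
        painted[py, px] = False
    return painted


def generate_roi_image(spec: SyntheticSpec) -> SyntheticSample:
    """Generate one masked-and-cropped synthetic ROI with exact ground truth.

    The painted fraction equals ``round(target_fraction * n_inside) /
    n_inside``, i.e. it matches the requested fraction to within half a pixel.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _make_mask(spec, rng)
    n_inside = int(mask.sum())
    target_pixels = int(round(spec.target_fraction * n_inside))
    min_stroke = spec.stroke_width**2
    if target_pixels < min_stroke:
        raise SyntheticSpecError(
            f"target fraction {spec.target_fraction} paints {target_pixels} pixels, "
            f"below one {spec.stroke_width}-px stroke footprint"
        )
    painted = _paint_strokes(mask, target_pixels, spec.stroke_width, rng)

    vmax = (1 << spec.bit_depth) - 1
    img = np.zeros((spec.height, spec.width), dtype=np.float64)
    noise = rng.normal(0.0, spec.noise_sd, size=img.shape)
    img[mask] = spec.background_mean + noise[mask]
    img[painted] = spec.signal_mean + noise[painted]
    pixels = np.zeros_like(img)
    pixels[mask] = np.clip(np.rint(img[mask]), 1, vmax)  # in-tissue pixels never 0
    gray = GrayImage(pixels.astype(np.uint8 if spec.bit_depth == 8 else np.uint16),
                     bit_depth=spec.bit_depth)
    roi = RoiMask(mask)
    truth = BinaryMap(painted.astype(np.uint8), roi, threshold_used=float("nan"))
    return SyntheticSample(gray, roi, truth, achieved_fraction=target_pixels / n_inside)


def apply_exposure_transform(
    img: GrayImage,
    gain: float = 1.0,
    clip_low: float = 0.0,
    clip_high: float | None = None,
) -> GrayImage:
    """Model exposure change, brightness boost and range clipping in one map.

    v -> round(clamp((gain*v - clip_low) / (clip_high - clip_low) * vmax)).
    ``clip_high`` defaults to the bit-depth maximum. With gain 1 and the full
    clip range this is the identity up to rounding. A ``clip_low`` above the
    background floor drives low in-mask pixels to 0 — the mask-shrinkage
    failure mode the control plots are there to catch.
    """
    vmax = img.max_value
    if clip_high is None:
        clip_high = float(vmax)
    if not clip_low < clip_high:
        raise ValueError("clip_low must be below clip_high")
    if gain <= 0:
        raise ValueError("gain must be positive")
    v = img.pixels.astype(np.float64)
    out = (gain * v - clip_low) / (clip_high - clip_low) * vmax
    out = np.clip(np.rint(out), 0, vmax)
    return GrayImage(out.astype(img.pixels.dtype), bit_depth=img.bit_depth)


def generate_stack(
    spec: SyntheticSpec, n_slices: int, visibility_span: int | None = None
) -> tuple[ImageStack, SyntheticSample]:
    """Generate a z-stack whose strokes are each visible in a contiguous slice run.

    The returned :class:`SyntheticSample` describes the *union* (flat) truth:
    its image is the noise-free union rendering's mask/geometry holder and its
    ``truth_signal`` is the union of per-slice painted pixels, which by
    construction equals the maximum-projection truth.
    """
    if n_slices < 1:
        raise SyntheticSpecError("a stack needs at least one slice")
    base = generate_roi_image(spec)
    if n_slices == 1:
        return ImageStack([base.image]), base

    rng = np.random.default_rng(spec.seed + 1)
    mask = base.truth_mask.inside
    painted = base.truth_signal.signal.astype(bool)
    coords = np.argwhere(painted)
    # split the painted pixels into connected stroke-ish chunks by ordering
    n_chunks = max(2, min(n_slices * 2, coords.shape[0] // 8 or 1))
    chunk_of = rng.integers(0, n_chunks, size=coords.shape[0])
    span = visibility_span if visibility_span is not None else max(1, n_slices // 2)

    per_slice_truth = [np.zeros_like(painted) for _ in range(n_slices)]
    for c in range(n_chunks):
        start = int(rng.integers(0, n_slices))
        stop = min(n_slices, start + span)
        pts = coords[chunk_of == c]
        for z in range(start, stop):
            per_slice_truth[z][pts[:, 0], pts[:, 1]] = True

    # every painted pixel must appear somewhere so the union truth is exact
    union = np.logical_or.reduce(per_slice_truth)
    missing = painted & ~union
    if missing.any():
        z = int(rng.integers(0, n_slices))
        per_slice_truth[z] |= missing

    vmax = (1 << spec.bit_depth) - 1
    slices = []
    for z in range(n_slices):
        noise = rng.normal(0.0, spec.noise_sd, size=mask.shape)
        img = np.zeros(mask.shape, dtype=np.float64)
        img[mask] = spec.background_mean + noise[mask]
        sel = per_slice_truth[z]
        img[sel] = spec.signal_mean + noise[sel]
        pixels = np.zeros_like(img)
        pixels[mask] = np.clip(np.rint(img[mask]), 1, vmax)
        slices.append(
            GrayImage(pixels.astype(np.uint8 if spec.bit_depth == 8 else np.uint16),
                      bit_depth=spec.bit_depth)
        )
    stack = ImageStack(slices)
    truth = SyntheticSample(
        base.image, base.truth_mask,
        BinaryMap(painted.astype(np.uint8), base.truth_mask, float("nan")),
        achieved_fraction=base.achieved_fraction,
    )
    return stack, truth


def make_nonfluorescent_pair(spec: SyntheticSpec) -> tuple[SyntheticSample, GrayImage]:
    """Emit a bright-axons ROI and its dark-on-light (DAB-like) twin.

    The dark twin is the exact intensity complement of the bright image, so
    the out-of-tissue surround sits at the bit-depth maximum (light) and
    inverting it restores the bright image — zeros, mask and all.
    """
    bright = generate_roi_image(spec)
    vmax = bright.image.max_value
    dark = GrayImage(vmax - bright.image.pixels, bit_depth=spec.bit_depth)
    return bright, dark


def spec_with_seed(spec: SyntheticSpec, seed: int) -> SyntheticSpec:
    """Convenience: the same recipe under a different seed."""
    return replace(spec, seed=seed)
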