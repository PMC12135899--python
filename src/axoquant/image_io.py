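"""TIFF reading/writing and elementary image transforms.

The analysis contract is built around integer TIFF images: single-channel or
RGB, 8- or 16-bit, single-page or multi-page (z-stacks). Pixels valued
exactly zero mark out-of-tissue space in masked-and-cropped ROIs, so every
transform here is written to preserve that convention: grayscale conversion
maps a pixel to zero iff all its channels are zero, and no operation ever
rescales intensities silently.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import EmptyStackError, UnsupportedFormatError, UnsupportedLayoutError

__all__ = [
    "RasterImage",
    "GrayImage",
    "ImageStack",
    "read_tiff",
    "write_tiff",
    "to_grayscale",
    "invert_intensity",
    "max_project",
]

_TIFF_EXTENSIONS = (".tif", ".tiff")


def _dtype_for(bit_depth: int):
    return np.uint8 if bit_depth == 8 else np.uint16


def _check_range(pixels: np.ndarray, bit_depth: int) -> None:
    if bit_depth not in (8, 16):
        raise UnsupportedFormatError(f"bit depth must be 8 or 16, got {bit_depth}")
    vmax = (1 << bit_depth) - 1
    if pixels.size == 0:
        raise UnsupportedFormatError("image has no pixels")
    if pixels.min() < 0 or pixels.max() > vmax:
        raise UnsupportedFormatError(
            f"intensities outside [0, {vmax}] for declared bit depth {bit_depth}"
        )


@dataclass
class RasterImage:
    """A raw raster as read from disk: 2-D grayscale or 3-D with RGB channels."""

    pixels: np.ndarray
    bit_depth: int
    source_path: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            pass
        elif self.pixels.ndim == 3:
            if self.pixels.shape[2] not in (1, 3):
                raise UnsupportedLayoutError(
                    f"expected 1 or 3 channels, got {self.pixels.shape[2]}"
                )
        else:
            raise UnsupportedLayoutError(
                f"expected a 2-D or 3-D pixel array, got ndim={self.pixels.ndim}"
            )
        _check_range(self.pixels, self.bit_depth)

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class GrayImage:
    """Single-channel integer image; the unit every analysis stage consumes."""

    pixels: np.ndarray
    bit_depth: int
    source_path: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise UnsupportedLayoutError("GrayImage pixels must be 2-D")
        _check_range(self.pixels, self.bit_depth)
        self.pixels = self.pixels.astype(_dtype_for(self.bit_depth), copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass
class ImageStack:
    """An ordered z-stack of same-shaped grayscale slices."""

    slices: list[GrayImage]
    z_step_um: float | None = None
    source_path: str = field(default="")

    def __post_init__(self) -> None:
        if not self.slices:
            raise EmptyStackError("a stack needs at least one slice")
        first = self.slices[0]
        for s in self.slices[1:]:
            if s.shape != first.shape or s.bit_depth != first.bit_depth:
                raise UnsupportedLayoutError("all stack slices must share shape and bit depth")
        if self.z_step_um is not None and self.z_step_um <= 0:
            raise ValueError("z_step_um must be positive")

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def bit_depth(self) -> int:
        return self.slices[0].bit_depth

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices[0].shape

    def as_array(self) -> np.ndarray:
        """(z, h, w) view of the stack."""
        return np.stack([s.pixels for s in self.slices], axis=0)


def _bit_depth_of(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    raise UnsupportedFormatError(
        f"unsupported sample format {arr.dtype}; only uint8/uint16 TIFFs are analyzable "
        "(float or palette data would corrupt the zero-pixel mask convention)"
    )


def read_tiff(path: str | os.PathLike) -> RasterImage | ImageStack:
    """Read a ``.tif``/``.tiff`` file into a :class:`RasterImage` or :class:`ImageStack`.

    Single-page files come back as :class:`RasterImage` (grayscale or RGB);
    multi-page grayscale files come back as :class:`ImageStack`. Pixel values
    are never rescaled.
    """
    path = os.fspath(path)
    if not str(path).lower().endswith(_TIFF_EXTENSIONS):
        raise UnsupportedFormatError(
            f"{path!r} is not a .tif file; images must be saved in the .tif format "
            "(animalID_brainregion_group_[additional_information].tif)"
        )
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        pages = [p.asarray() for p in tf.pages]
    if len(pages) == 1:
        arr = pages[0]
        return RasterImage(arr, bit_depth=_bit_depth_of(arr), source_path=str(path))
    depth = _bit_depth_of(pages[0])
    slices = []
    for arr in pages:
        if arr.ndim == 3:  # RGB pages are reduced so stacks stay grayscale
            arr = to_grayscale(RasterImage(arr, _bit_depth_of(arr))).pixels
        slices.append(GrayImage(arr, bit_depth=depth))
    return ImageStack(slices, source_path=str(path))


def write_tiff(path: str | os.PathLike, img: RasterImage | GrayImage | ImageStack) -> None:
    """Write an image or stack as an uncompressed TIFF (bit-exact round trip)."""
    path = os.fspath(path)
    if isinstance(img, ImageStack):
        tifffile.imwrite(path, img.as_array(), photometric="minisblack")
    else:
        tifffile.imwrite(path, img.pixels)


def to_grayscale(img: RasterImage) -> GrayImage:
    """Reduce a raster to one channel.

    Single-channel input passes through bit-exact. RGB input is reduced by the
    per-pixel channel *maximum*: fluorescence lives in one channel, so a max
    keeps the signal on its native scale regardless of fluorophore, and a pixel
    is zero in the output iff it is zero in every channel — exactly the
    zero-pixel mask semantics require.
    """
    if img.n_channels == 1:
        arr = img.pixels if img.pixels.ndim == 2 else img.pixels[:, :, 0]
        return GrayImage(arr.copy(), bit_depth=img.bit_depth, source_path=img.source_path)
    if img.n_channels == 3:
        return GrayImage(
            img.pixels.max(axis=2), bit_depth=img.bit_depth, source_path=img.source_path
        )
    raise UnsupportedLayoutError(f"cannot convert {img.n_channels}-channel image")


def invert_intensity(img: GrayImage) -> GrayImage:
    """Map each pixel v to ``(2^bit_depth - 1) - v``.

    Used for nonfluorescent (e.g. DAB) stains where axons are dark on a light
    background: inversion makes them bright on dark so the standard pipeline
    applies. Apply *before* mask derivation — inversion maps the light
    out-of-tissue surround to 0.
    """
    return GrayImage(
        img.max_value - img.pixels, bit_depth=img.bit_depth, source_path=img.source_path
    )


def max_project(stack: ImageStack) -> GrayImage:
    """Maximum intensity projection: per-pixel maximum over the z axis."""
    return GrayImage(
        stack.as_array().max(axis=0), bit_depth=stack.bit_depth, source_path=stack.source_path
    )
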