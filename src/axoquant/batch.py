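"""Batch discovery, filename parsing, per-image pipeline and CSV outputs.

Filenames carry the experimental design: ``animalID_brainregion_group`` plus
optional trailing tokens, split on underscores. A batch run walks a folder of
``.tif`` files in sorted order, runs the full pipeline on each (read ->
grayscale -> optional invert -> mask -> Otsu -> binarize -> quantify ->
profiles), skips and logs images that fail (bad name, uniform ROI), and
writes two CSVs: per-image measurements and long-format axis profiles.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AxoquantError, EmptyBatchError, NamingConventionError
from .image_io import GrayImage, ImageStack, invert_intensity, max_project, read_tiff, to_grayscale
from .profiles import binary_axis_counts, grayscale_axis_means
from .segmentation import (
    BinaryMap,
    RegionMeasurement,
    RoiMask,
    binarize,
    derive_mask,
    otsu_threshold,
    quantify_region,
)

__all__ = [
    "SampleKey",
    "BatchConfig",
    "ImageAnalysis",
    "BatchResult",
    "parse_sample_name",
    "analyze_image",
    "run_batch",
    "summarize_by_region",
    "write_outputs",
]

logger = logging.getLogger("axoquant")

MEASUREMENT_COLUMNS = [
    "filename", "animal_id", "brain_region", "group", "signal_pct",
    "area", "area_units", "threshold", "mask_pixels", "pixel_size_um",
]
PROFILE_COLUMNS = [
    "filename", "animal_id", "brain_region", "group", "axis", "kind", "index", "value",
]


@dataclass(frozen=True)
class SampleKey:
    """Animal / region / group identity parsed from a filename stem."""

    animal_id: str
    brain_region: str
    group: str
    extras: tuple[str, ...] = ()


@dataclass
class BatchConfig:
    """Knobs for one batch run."""

    input_dir: str | os.PathLike
    output_dir: str | os.PathLike
    pixel_size_um: float | None = None
    masked_mode: bool = True
    invert_mode: bool = False
    random_seed: int = 0
    write_figures: bool = True

    def __post_init__(self) -> None:
        if not Path(self.input_dir).is_dir():
            raise FileNotFoundError(f"input_dir {self.input_dir} does not exist")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class ImageAnalysis:
    """Everything the pipeline computed for one image (control-plot input)."""

    key: SampleKey
    filename: str
    gray: GrayImage
    mask: RoiMask
    binary: BinaryMap
    measurement: RegionMeasurement
    profiles: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class BatchResult:
    measurements: pd.DataFrame
    profiles: pd.DataFrame
    analyses: list[ImageAnalysis]
    skipped: list[tuple[str, str]]  # (filename, reason)


def parse_sample_name(filename: str) -> SampleKey:
    """Split a ``.tif`` filename stem on underscores into (animal, region, group).

    Tokens after the third are stored but ignored by the analysis.
    """
    name = os.path.basename(str(filename))
    if not name.lower().endswith((".tif", ".tiff")):
        raise NamingConventionError(f"{name!r} is not a .tif file")
    stem = name.rsplit(".", 1)[0]
    tokens = stem.split("_")
    if len(tokens) < 3 or any(t == "" for t in tokens[:3]):
        raise NamingConventionError(
            f"{name!r} does not follow the naming convention "
            "animalID_brainregion_group_[additional_information].tif"
        )
    return SampleKey(tokens[0], tokens[1], tokens[2], tuple(tokens[3:]))


def analyze_image(
    gray: GrayImage,
    key: SampleKey,
    masked_mode: bool = True,
    invert_mode: bool = False,
    pixel_size_um: float | None = None,
    filename: str = "",
) -> ImageAnalysis:
    """Run the core pipeline on one grayscale image."""
    if invert_mode:
        gray = invert_intensity(gray)
    mask = derive_mask(gray, masked_mode=masked_mode)
    th = otsu_threshold(gray, mask)
    binary = binarize(gray, mask, th)
    meas = quantify_region(
        binary, mask, key.animal_id, key.brain_region, key.group,
        pixel_size_um=pixel_size_um, filename=filename,
    )
    bx, by = binary_axis_counts(binary, mask)
    gx, gy = grayscale_axis_means(gray, mask)
    return ImageAnalysis(
        key=key, filename=filename, gray=gray, mask=mask, binary=binary,
        measurement=meas,
        profiles={"binary_x": bx.values, "binary_y": by.values,
                  "gray_x": gx.values, "gray_y": gy.values},
    )


def _profile_rows(a: ImageAnalysis) -> list[dict]:
    rows = []
    for tag, kind, axis in (
        ("binary_x", "binary-count", "x"), ("binary_y", "binary-count", "y"),
        ("gray_x", "grayscale-mean", "x"), ("gray_y", "grayscale-mean", "y"),
    ):
        vals = a.profiles[tag]
        for i, v in enumerate(vals):
            rows.append({
                "filename": a.filename, "animal_id": a.key.animal_id,
                "brain_region": a.key.brain_region, "group": a.key.group,
                "axis": axis, "kind": kind, "index": i, "value": v,
            })
    return rows


def run_batch(cfg: BatchConfig) -> BatchResult:
    """Process every ``.tif`` in ``cfg.input_dir`` (sorted by filename).

    Per-image failures are logged and skipped; only an empty batch is fatal.
    Multi-page files are reduced to their first page with a warning — the
    batch workflow expects pre-made 2-D maximal projections (use the z-stack
    API for true stack analysis).
    """
    in_dir = Path(cfg.input_dir)
    files = sorted(
        p for p in in_dir.iterdir()
        if p.is_file() and p.suffix.lower() in (".tif", ".tiff")
    )
    if not files:
        raise EmptyBatchError(f"no .tif files found in {in_dir}")

    analyses: list[ImageAnalysis] = []
    skipped: list[tuple[str, str]] = []
    for path in files:
        try:
            key = parse_sample_name(path.name)
            img = read_tiff(path)
            if isinstance(img, ImageStack):
                logger.warning("%s: multi-page TIFF in batch mode; using page 1 only", path.name)
                gray = img.slices[0]
            else:
                gray = to_grayscale(img)
            analyses.append(
                analyze_image(
                    gray, key,
                    masked_mode=cfg.masked_mode, invert_mode=cfg.invert_mode,
                    pixel_size_um=cfg.pixel_size_um, filename=path.name,
                )
            )
        except (AxoquantError, FileNotFoundError) as exc:
            logger.warning("skipping %s: %s", path.name, exc)
            skipped.append((path.name, str(exc)))
    if not analyses:
        raise EmptyBatchError(f"no processable images in {in_dir} ({len(skipped)} skipped)")

    meas_rows = []
    for a in analyses:
        m = a.measurement
        meas_rows.append({
            "filename": a.filename, "animal_id": m.animal_id,
            "brain_region": m.brain_region, "group": m.group,
            "signal_pct": m.signal_pct, "area": m.area, "area_units": m.area_units,
            "threshold": m.threshold_used, "mask_pixels": m.mask_pixels,
            "pixel_size_um": m.pixel_size_um,
        })
    measurements = pd.DataFrame(meas_rows, columns=MEASUREMENT_COLUMNS)
    profile_rows: list[dict] = []
    for a in analyses:
        profile_rows.extend(_profile_rows(a))
    profiles = pd.DataFrame(profile_rows, columns=PROFILE_COLUMNS)
    return BatchResult(measurements, profiles, analyses, skipped)


def summarize_by_region(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per (region, group) mean +/- SEM of signal %, area and threshold.

    Each animal contributes once: images of the same animal/region/group are
    averaged first, so n is the number of animals (the dots on the summary
    plot), not the number of images. SEM is the sample SD (n-1) over sqrt(n);
    with a single animal it is reported as 0 and flagged.
    """
    if measurements.empty:
        raise EmptyBatchError("cannot summarize an empty measurements table")
    animal_level = (
        measurements
        .groupby(["brain_region", "group", "animal_id"], as_index=False)
        [["signal_pct", "area", "threshold"]]
        .mean()
    )
    rows = []
    for (region, group), g in animal_level.groupby(["brain_region", "group"]):
        n = len(g)
        row = {"brain_region": region, "group": group, "n_animals": n,
               "single_animal": n == 1}
        for col in ("signal_pct", "area", "threshold"):
            row[f"{col}_mean"] = g[col].mean()
            row[f"{col}_sem"] = 0.0 if n == 1 else g[col].std(ddof=1) / np.sqrt(n)
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["brain_region", "group"]).reset_index(drop=True)


def write_outputs(result: BatchResult, output_dir: str | os.PathLike) -> dict[str, Path]:
    """Write ``measurements.csv`` and ``axis_profiles.csv`` (UTF-8, '.' decimals).

    Row order follows the sorted-by-filename processing order, so re-running
    on the same folder is byte-identical.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "measurements": out / "measurements.csv",
        "profiles": out / "axis_profiles.csv",
    }
    result.measurements.to_csv(paths["measurements"], index=False, encoding="utf-8")
    result.profiles.to_csv(paths["profiles"], index=False, encoding="utf-8")
    return paths
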