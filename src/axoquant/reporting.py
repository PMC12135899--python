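"""PDF figures: per-image control plots, summary bars, and axis-profile plots.

All figures are vector PDFs so they can be post-edited in an illustration
tool. Nothing here computes new statistics: every number shown is
recomputable from the two CSVs the batch writes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .batch import ImageAnalysis, summarize_by_region
from .profiles import AxisProfile, normalize_profile

__all__ = [
    "ControlPlotSpec",
    "control_spec_from_analysis",
    "render_control_plot",
    "render_summary_figure",
    "render_axis_summary",
    "resample_profile",
]


@dataclass
class ControlPlotSpec:
    """Inputs for one four-quadrant control plot."""

    title: str
    gray_pixels: np.ndarray
    mask_pixels: np.ndarray
    binary_pixels: np.ndarray
    gray_x: np.ndarray
    gray_y: np.ndarray
    binary_x: np.ndarray
    binary_y: np.ndarray
    signal_pct: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.signal_pct <= 100.0:
            raise ValueError("signal_pct must be a percentage")


def control_spec_from_analysis(a: ImageAnalysis) -> ControlPlotSpec:
    key = a.key
    return ControlPlotSpec(
        title=f"{key.animal_id} | {key.brain_region} | {key.group}",
        gray_pixels=a.gray.pixels,
        mask_pixels=a.mask.inside,
        binary_pixels=a.binary.signal,
        gray_x=a.profiles["gray_x"],
        gray_y=a.profiles["gray_y"],
        binary_x=a.profiles["binary_x"],
        binary_y=a.profiles["binary_y"],
        signal_pct=a.measurement.signal_pct,
    )


def _panel_with_margins(fig, pos):
    """An image axis plus thin marginal axes below (x) and left (y)."""
    gs = pos.subgridspec(2, 2, width_ratios=[1, 5], height_ratios=[5, 1],
                         wspace=0.05, hspace=0.05)
    ax_img = fig.add_subplot(gs[0, 1])
    ax_x = fig.add_subplot(gs[1, 1], sharex=ax_img)
    ax_y = fig.add_subplot(gs[0, 0], sharey=ax_img)
    for ax in (ax_img, ax_x, ax_y):
        ax.tick_params(labelsize=6)
    return ax_img, ax_x, ax_y


def render_control_plot(spec: ControlPlotSpec, out_path: str | Path) -> Path:
    """One-page PDF: grayscale + its axis signals, mask + extents, binarized
    image + axis signals, and a signal/background pie."""
    fig = plt.figure(figsize=(10, 8))
    fig.suptitle(spec.title, fontsize=11)
    outer = fig.add_gridspec(2, 2, hspace=0.3, wspace=0.25)

    ax, axx, axy = _panel_with_margins(fig, outer[0, 0])
    ax.imshow(spec.gray_pixels, cmap="gray", aspect="auto")
    ax.set_title("grayscale", fontsize=9)
    axx.plot(spec.gray_x, lw=0.8)
    axy.plot(spec.gray_y, np.arange(spec.gray_y.size), lw=0.8)
    axy.invert_xaxis()

    ax, axx, axy = _panel_with_margins(fig, outer[1, 0])
    ax.imshow(spec.mask_pixels, cmap="gray", aspect="auto")
    ax.set_title("mask", fontsize=9)
    axx.plot(spec.mask_pixels.sum(axis=0), lw=0.8)  # mask extent along x
    axy.plot(spec.mask_pixels.sum(axis=1), np.arange(spec.mask_pixels.shape[0]), lw=0.8)
    axy.invert_xaxis()

    ax, axx, axy = _panel_with_margins(fig, outer[0, 1])
    ax.imshow(spec.binary_pixels, cmap="gray", aspect="auto", vmin=0, vmax=1)
    ax.set_title("binarized", fontsize=9)
    axx.plot(spec.binary_x, lw=0.8)
    axy.plot(spec.binary_y, np.arange(spec.binary_y.size), lw=0.8)
    axy.invert_xaxis()

    ax = fig.add_subplot(outer[1, 1])
    background_pct = 100.0 - spec.signal_pct
    ax.pie(
        [spec.signal_pct, background_pct],
        labels=[f"signal {spec.signal_pct:.1f}%", f"background {background_pct:.1f}%"],
        colors=["white", "dimgray"], wedgeprops={"edgecolor": "black"},
        textprops={"fontsize": 8},
    )
    ax.set_title("quantification", fontsize=9)

    out_path = Path(out_path)
    fig.savefig(out_path, format="pdf")
    plt.close(fig)
    return out_path


def render_summary_figure(measurements: pd.DataFrame, out_path: str | Path,
                          seed: int = 0) -> Path:
    """Three bar panels (signal %, area, threshold): bar = mean, whisker = SEM
    across animals, dots = individual animals (jittered)."""
    summary = summarize_by_region(measurements)
    animal_level = (
        measurements
        .groupby(["brain_region", "group", "animal_id"], as_index=False)
        [["signal_pct", "area", "threshold"]]
        .mean()
    )
    rng = np.random.default_rng(seed)
    panels = [("signal_pct", "signal (%)"), ("area", "ROI area"),
              ("threshold", "binarization threshold")]
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    labels = [f"{r}\n{g}" for r, g in zip(summary["brain_region"], summary["group"])]
    xs = np.arange(len(summary))
    for ax, (col, title) in zip(axes, panels):
        sem = summary[f"{col}_sem"].to_numpy()
        ax.bar(xs, summary[f"{col}_mean"], yerr=sem, capsize=3,
               color="lightsteelblue", edgecolor="black")
        for i, row in summary.iterrows():
            pts = animal_level[
                (animal_level["brain_region"] == row["brain_region"])
                & (animal_level["group"] == row["group"])
            ][col]
            jitter = rng.uniform(-0.15, 0.15, size=len(pts))
            ax.plot(np.full(len(pts), i) + jitter, pts, "o", color="black", ms=4)
        ax.set_xticks(xs)
        ax.set_xticklabels(labels, fontsize=7)
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, format="pdf")
    plt.close(fig)
    return out_path


def resample_profile(values: np.ndarray, n_points: int = 100) -> np.ndarray:
    """Linear-interpolation resampling to a common length.

    ROIs differ in pixel dimensions, so cross-animal mean +/- SEM traces need
    profiles on a shared grid first.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return np.zeros(n_points)
    if values.size == 1:
        return np.full(n_points, values[0])
    return np.interp(
        np.linspace(0, values.size - 1, n_points), np.arange(values.size), values
    )


def render_axis_summary(profiles: pd.DataFrame, out_path: str | Path,
                        n_points: int = 100) -> Path:
    """Per region: normalized binary x/y profiles; gray per-animal traces plus
    the mean +/- SEM band across animals."""
    binary = profiles[profiles["kind"] == "binary-count"]
    regions = sorted(binary["brain_region"].unique())
    fig, axes = plt.subplots(len(regions), 2, figsize=(9, 3 * len(regions)),
                             squeeze=False)
    grid = np.linspace(0, 1, n_points)
    for r_i, region in enumerate(regions):
        for a_i, axis in enumerate(("x", "y")):
            ax = axes[r_i, a_i]
            sub = binary[(binary["brain_region"] == region) & (binary["axis"] == axis)]
            traces = []
            for animal, g in sub.groupby("animal_id"):
                # an animal may contribute several images: average its profiles
                per_file = [
                    resample_profile(fg.sort_values("index")["value"].to_numpy(), n_points)
                    for _, fg in g.groupby("filename")
                ]
                trace = np.mean(per_file, axis=0)
                prof = normalize_profile(AxisProfile(axis, trace, "binary-count"))
                traces.append(prof.values.astype(float))
                ax.plot(grid, traces[-1], color="gray", lw=0.8)
            arr = np.asarray(traces, dtype=float)
            mean = arr.mean(axis=0)
            sem = (arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
                   if arr.shape[0] > 1 else np.zeros(n_points))
            ax.plot(grid, mean, color="tab:blue", lw=1.5)
            ax.fill_between(grid, mean - sem, mean + sem, color="tab:blue", alpha=0.3)
            ax.set_title(f"{region} — {axis} axis", fontsize=9)
            ax.set_ylabel("normalized signal", fontsize=8)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, format="pdf")
    plt.close(fig)
    return out_path
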