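# Methods

## Model and assumptions

The quantity of interest is the innervation percentage of a brain region of
interest: the fraction of in-tissue pixels occupied by labeled axons. The
method assumes

* the ROI was delineated, masked and cropped upstream (atlas overlay and
  drawing happen in external software), with out-of-tissue pixels stored as
  exactly zero and in-tissue background fluorescence strictly positive;
* intensities are 8- or 16-bit integers; any RGB image carries its signal in
  channel intensities, not in hue;
* axon and background intensity distributions are separable ("adequate
  signal-to-noise"): the method thresholds *whatever* histogram it is given,
  so an ROI with no axons at all will still be split into two classes — the
  per-image control plot, not the algorithm, is the guard against that.

No attempt is made to distinguish axons from somata or artifacts, to trace
axon length, or to threshold locally/adaptively.

## Thresholding details

The Otsu criterion is implemented directly on the in-mask histogram:

* **8-bit** — exact integer bins 0..255. Candidate cuts are every integer
  `t`; class 0 is `v <= t`, class 1 is `v > t` (a pixel equal to the
  threshold is background — the strictly-above reading).
* **16-bit** — 256 equal-width bins spanning the observed in-mask min..max.
  Class statistics use the exact per-bin value sums, not bin centers. The
  returned threshold is the largest integer strictly below the argmax bin's
  exclusive upper edge, so `v > t` reproduces the bin split exactly on
  integer data while remaining a native-scale intensity.
* **Ties** — among cuts whose between-class variance is within a relative
  1e-12 of the maximum (exact mathematical plateaus, e.g. over empty bins,
  perturbed only by float round-off), the lowest cut wins. Deterministic
  and sensitivity-favoring.
* **Degenerate input** — a constant in-mask ROI raises a hard error rather
  than returning 0 %: a uniform ROI nearly always means a broken export,
  and a silent zero would hide it.

Out-of-mask pixels never enter the histogram, so the threshold is invariant
to how much zero padding surrounds the tissue and to any permutation of
pixel positions.

Z-stacks are thresholded once, globally, on the pooled in-mask histogram of
all slices. Three percentages are reported: per-slice / 3-D (signal voxels
over in-mask voxels of all slices), flat (union of binarized slices), and
the binarized maximum intensity projection. The flat map equals the
binarized MIP pixel-for-pixel (a per-pixel maximum commutes with a fixed
cut), and the 3-D percentage is bounded above by the flat one.

## Parameters

| parameter | unit | default | role |
|---|---|---|---|
| `pixel_size_um` | µm/pixel | none | converts mask pixel counts to µm² areas; without it areas stay in pixels and are flagged. No numeric default is fabricated because it depends on the user's objective and camera. |
| `masked_mode` | flag | true | zeros = out-of-tissue. Unmasked mode analyzes the full rectangle and keeps zeros as data. |
| `invert_mode` | flag | false | for dark-on-light nonfluorescent stains; inversion precedes mask derivation. |
| `random_seed` | int | 0 | plot-point jitter only; no analysis step is stochastic. |

## Aggregation

Summary statistics collapse to animal-level means per (region, group) first,
then take mean and SEM (sample SD, n−1, over √n) across animals — the dots
on the summary figure are animals, and image-level SEM would inflate n. A
single-animal cell reports SEM 0 with an explicit flag. Cross-animal axis
profiles are resampled to a common length (default 100 points, linear
interpolation) before normalization to their maximum and averaging, because
ROIs differ in pixel dimensions; the CSV stores the raw, unnormalized
profiles from which all of this is re-derivable.

## Synthetic fixtures

The generator emulates exactly the contract above: an elliptical, random
star-polygon, or full-frame tissue mask; background pixels
Normal(µ_bg = 40, σ = 10) and axon strokes Normal(µ_sig = 200, σ = 10) on
the 8-bit scale, rounded and clamped to [1, 255] inside the mask (zero
outside), so no in-tissue pixel is ever zero. The 16-SD separation between
the class means is an unambiguous signal-to-noise regime — the defaults
describe a cleanly acquired image. Axons are constant-width random-walk
polylines painted until an exact target fraction of in-mask pixels is hit
(the walk tail is trimmed on overshoot, so the achieved fraction equals
`round(f·n_inside)/n_inside`); ground truth is therefore exact. Test images
are 128×160 pixels (stacks 64×80), sizes at which every suite and the
validation script complete in seconds while leaving thousands of mask
pixels per image.

What the generator does **not** emulate: point-spread blur, branching or
varicose axon morphology, somata, autofluorescent artifacts, uneven
illumination, or correlated noise. Passing tests therefore demonstrate the
*algorithmic* correctness of masking, thresholding, counting and
bookkeeping on separable data — not performance on low-SNR tissue, which
the exposure-transform tests probe only coarsely (gain, saturation and
clipping applied to clean fixtures).

The exposure operator `v → round(clamp((g·v − c_lo)/(c_hi − c_lo) · vmax))`
models gain, brightness boosts and range clipping in one map. It reproduces
the documented failure modes: pinning ≥20 % of in-mask pixels at the
maximum inflates the measured percentage; clipping the low end to zero
shrinks the mask and inflates the percentage via the smaller denominator.
Under a pure gain with no saturation the readout is stable to well under
half a percentage point.

## Design choices that were genuinely open

* **RGB→gray by channel maximum** (not luminance weights): luminance would
  scale signal differently per fluorophore and could zero out a colored
  pixel; the maximum preserves both fluorophore independence and the
  zero-pixel convention.
* **Multi-page TIFFs in batch mode** use page 1 with a warning; the batch
  contract expects pre-made 2-D projections, and silent 3-D analysis would
  change the denominator semantics. Explicit stack analysis goes through
  the stack API.
* **Float/palette TIFFs are rejected**, never coerced: rescaling would
  corrupt the zero-pixel convention.
* **CSV schemas** (`measurements.csv`, long-format `axis_profiles.csv`)
  are this package's own definition; rows are ordered by filename so reruns
  are byte-identical.

## Known limitations

Bright empty ROIs still get segmented (inspect control plots); touching
axons are counted as area, not number; the 16-bit observed-range binning
means thresholds from images with different dynamic ranges are not directly
comparable across images (percentages are); and inter-researcher
variability of the upstream manual masking step is outside what synthetic
data can measure.
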