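"""How acquisition/post-acquisition changes move (or don't move) the readout.

Three scenarios on one ground-truthed fixture:

* a pure gain with no saturation — the dynamic threshold scales with the
  histogram, so the percentage barely moves;
* overexposure (pixels pinned at the maximum) — information is destroyed and
  the percentage inflates;
* clipping the low end to zero — background pixels drop out of the mask, the
  denominator shrinks, and the percentage overestimates.

The last two are exactly the failure modes the per-image control plots are
meant to reveal.
"""

from axoquant import (
    SyntheticSpec,
    apply_exposure_transform,
    binarize,
    derive_mask,
    generate_roi_image,
    otsu_threshold,
)


def measure(img):
    mask = derive_mask(img)
    b = binarize(img, mask, otsu_threshold(img, mask))
    return 100.0 * b.n_signal / mask.n_inside, mask.n_inside


s = generate_roi_image(SyntheticSpec(seed=11, signal_mean=100.0, noise_sd=5.0))
base, n0 = measure(s.image)
print(f"baseline            : P = {base:.3f} %  (mask {n0} px)")

for gain in (1.2, 1.5, 2.0):
    pct, n = measure(apply_exposure_transform(s.image, gain=gain))
    print(f"gain {gain:.1f} (no satur.): P = {pct:.3f} %  (mask {n} px)")

pct, n = measure(apply_exposure_transform(s.image, clip_high=42.0))
print(f"overexposed         : P = {pct:.3f} %  (mask {n} px)  <- inflated")

pct, n = measure(apply_exposure_transform(s.image, clip_low=40.0))
print(f"low end clipped     : P = {pct:.3f} %  (mask {n} px)  <- mask shrank")
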