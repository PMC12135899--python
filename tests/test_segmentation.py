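"""Masking, in-mask Otsu, binarization, quantification, stack variants."""

import numpy as np
import pytest

from axoquant import (
    EmptyRoiError,
    GrayImage,
    ImageStack,
    RoiMask,
    SyntheticSpec,
    UniformRoiError,
    apply_exposure_transform,
    binarize,
    derive_mask,
    generate_roi_image,
    generate_stack,
    max_project,
    otsu_threshold,
    quantify_region,
    stack_global_threshold,
    stack_quantify,
)
from axoquant.segmentation import _otsu_from_values

from conftest import otsu_brute_force, random_bimodal_values


def _gray(values, bit_depth=8):
    return GrayImage(np.asarray(values, dtype=np.uint8 if bit_depth == 8 else np.uint16),
                     bit_depth=bit_depth)


class TestDeriveMask:
    def test_zero_border_defines_interior_mask(self):
        px = np.zeros((5, 5), dtype=np.uint8)
        px[1:4, 1:4] = 50
        mask = derive_mask(_gray(px), masked_mode=True)
        assert mask.n_inside == 9
        np.testing.assert_array_equal(mask.inside, px > 0)

    def test_unmasked_mode_takes_everything(self):
        px = np.zeros((4, 6), dtype=np.uint8)
        assert derive_mask(_gray(px), masked_mode=False).n_inside == 24

    def test_all_zero_image_is_empty_roi(self):
        with pytest.raises(EmptyRoiError):
            derive_mask(_gray(np.zeros((4, 4), dtype=np.uint8)), masked_mode=True)

    def test_low_end_clipping_shrinks_the_mask(self, sample):
        baseline = derive_mask(sample.image).n_inside
        clipped = apply_exposure_transform(sample.image, clip_low=40.0)
        assert derive_mask(clipped).n_inside < baseline


class TestOtsuThreshold:
    def test_two_point_histogram_lowest_tie(self):
        px = np.concatenate([np.full(50, 10), np.full(50, 200)]).astype(np.uint8)
        img = _gray(px.reshape(10, 10))
        mask = RoiMask(np.ones((10, 10), dtype=bool))
        th = otsu_threshold(img, mask)
        assert th.threshold == 10  # every cut in [10, 200) ties; lowest wins
        b = binarize(img, mask, th)
        assert b.n_signal == 50
        np.testing.assert_array_equal(b.signal.ravel(), (px == 200).astype(np.uint8))

    def test_constant_roi_is_an_error(self):
        img = _gray(np.full((5, 5), 80, dtype=np.uint8))
        with pytest.raises(UniformRoiError):
            otsu_threshold(img, RoiMask(np.ones((5, 5), dtype=bool)))

    def test_out_of_mask_pixels_never_enter_the_histogram(self):
        rng = np.random.default_rng(4)
        px = random_bimodal_values(rng, 2)[:100].reshape(10, 10)
        mask = np.zeros((10, 10), dtype=bool)
        mask[:, :5] = True
        img = _gray(px)
        th = otsu_threshold(img, RoiMask(mask))
        # corrupting out-of-mask pixels must not change the threshold
        px2 = px.copy()
        px2[:, 5:] = 255
        th2 = otsu_threshold(_gray(px2), RoiMask(mask))
        assert th.threshold == th2.threshold
        assert th.between_class_variance == th2.between_class_variance

    def test_matches_exhaustive_oracle_on_random_histograms(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            v = random_bimodal_values(rng)
            assert _otsu_from_values(v, 8).threshold == otsu_brute_force(v)

    def test_matches_skimage_on_separated_data(self):
        """Independent cross-check against the reference Otsu implementation."""
        skimage = pytest.importorskip("skimage.filters")
        rng = np.random.default_rng(7)
        for _ in range(20):
            v = np.concatenate(
                [rng.normal(60, 15, 800), rng.normal(190, 12, 300)]
            )
            v = np.clip(np.rint(v), 1, 255).astype(np.uint8)
            assert _otsu_from_values(v, 8).threshold == skimage.threshold_otsu(v)

    def test_class_statistics_are_consistent(self):
        rng = np.random.default_rng(9)
        v = random_bimodal_values(rng, 2)
        th = _otsu_from_values(v, 8)
        w0, w1 = th.class_weights
        mu0, mu1 = th.class_means
        assert w0 + w1 == pytest.approx(1.0)
        assert 0 < w0 < 1 and mu0 < mu1
        assert th.between_class_variance == pytest.approx(w0 * w1 * (mu0 - mu1) ** 2)
        assert v.min() <= th.threshold < v.max()

    def test_16bit_threshold_splits_classes_of_separated_fixture(self):
        spec = SyntheticSpec(seed=5, bit_depth=16, background_mean=600.0,
                             signal_mean=3000.0, noise_sd=120.0)
        s = generate_roi_image(spec)
        mask = derive_mask(s.image)
        th = otsu_threshold(s.image, mask)
        assert 600.0 < th.threshold < 3000.0
        b = binarize(s.image, mask, th)
        measured = b.n_signal / mask.n_inside
        assert measured == pytest.approx(s.achieved_fraction, abs=0.005)

    def test_position_permutation_leaves_threshold_unchanged(self, sample):
        mask = derive_mask(sample.image)
        th = otsu_threshold(sample.image, mask)
        rng = np.random.default_rng(0)
        perm = rng.permutation(sample.image.pixels.size)
        px = sample.image.pixels.ravel()[perm].reshape(sample.image.shape)
        m = mask.inside.ravel()[perm].reshape(mask.shape)
        th2 = otsu_threshold(_gray(px), RoiMask(m))
        assert th2.threshold == th.threshold
        assert th2.between_class_variance == pytest.approx(th.between_class_variance)


class TestBinarize:
    def test_threshold_boundary_is_background(self):
        img = _gray(np.array([[10, 11]], dtype=np.uint8))
        mask = RoiMask(np.ones((1, 2), dtype=bool))
        th = otsu_threshold(img, mask)
        assert th.threshold == 10
        b = binarize(img, mask, th)
        assert b.signal[0, 0] == 0 and b.signal[0, 1] == 1

    def test_saturated_case_fills_the_mask(self, sample):
        mask = derive_mask(sample.image)
        th = otsu_threshold(sample.image, mask)
        bright = GrayImage(np.full(sample.image.shape, 255, np.uint8), 8)
        b = binarize(bright, mask, th)
        assert b.n_signal == mask.n_inside

    def test_zero_outside_mask(self, sample):
        mask = derive_mask(sample.image)
        b = binarize(sample.image, mask, otsu_threshold(sample.image, mask))
        assert not b.signal[~mask.inside].any()

    def test_dimension_mismatch_rejected(self, sample):
        mask = derive_mask(sample.image)
        th = otsu_threshold(sample.image, mask)
        with pytest.raises(ValueError):
            binarize(_gray(np.ones((2, 2), np.uint8)), mask, th)

    def test_recovers_painted_fraction(self, sample):
        mask = derive_mask(sample.image)
        b = binarize(sample.image, mask, otsu_threshold(sample.image, mask))
        assert b.n_signal / mask.n_inside == pytest.approx(0.10, abs=0.02)


class TestQuantifyRegion:
    def _binary(self, n_signal, n_total):
        mask = RoiMask(np.ones((1, n_total), dtype=bool))
        sig = np.zeros((1, n_total), dtype=np.uint8)
        sig[0, :n_signal] = 1
        from axoquant.segmentation import BinaryMap

        return BinaryMap(sig, mask, threshold_used=42), mask

    def test_percentage_arithmetic(self):
        b, mask = self._binary(25, 100)
        m = quantify_region(b, mask)
        assert m.signal_pct == 25.0
        assert m.threshold_used == 42

    def test_area_with_pixel_size(self):
        b, mask = self._binary(0, 100)
        m = quantify_region(b, mask, pixel_size_um=2.0)
        assert m.area == 400.0 and m.area_units == "um^2"

    def test_area_fallback_is_pixels(self):
        b, mask = self._binary(0, 100)
        m = quantify_region(b, mask)
        assert m.area == 100.0 and m.area_units == "pixel"

    def test_conservation_is_exact(self, sample):
        mask = derive_mask(sample.image)
        b = binarize(sample.image, mask, otsu_threshold(sample.image, mask))
        m = quantify_region(b, mask)
        assert m.signal_pct * m.mask_pixels / 100.0 == pytest.approx(b.n_signal, abs=1e-9)


class TestStackOperations:
    def test_single_slice_pooling_matches_2d_threshold(self, sample):
        mask = derive_mask(sample.image)
        th2d = otsu_threshold(sample.image, mask)
        th3d = stack_global_threshold(ImageStack([sample.image]), mask)
        assert th3d.threshold == th2d.threshold

    def test_identical_slices_share_the_single_slice_threshold(self, sample):
        mask = derive_mask(sample.image)
        th1 = otsu_threshold(sample.image, mask)
        thn = stack_global_threshold(ImageStack([sample.image] * 3), mask)
        assert thn.threshold == th1.threshold

    def test_pooled_histogram_matches_oracle(self):
        stack, truth = generate_stack(SyntheticSpec(seed=21), 3)
        mask = truth.truth_mask
        pooled = stack.as_array()[:, mask.inside].ravel()
        th = stack_global_threshold(stack, mask)
        assert th.threshold == otsu_brute_force(pooled)

    def test_single_slice_stack_degenerates(self, sample):
        mask = derive_mask(sample.image)
        per_slice, p3d, pflat = stack_quantify(ImageStack([sample.image]), mask)
        assert len(per_slice) == 1
        assert p3d == pflat == per_slice[0].signal_pct

    def test_flat_binary_equals_binarized_mip(self):
        stack, truth = generate_stack(SyntheticSpec(seed=22), 4)
        mask = truth.truth_mask
        th = stack_global_threshold(stack, mask)
        flat = np.maximum.reduce(
            [binarize(sl, mask, th).signal for sl in stack.slices]
        )
        mip_b = binarize(max_project(stack), mask, th)
        np.testing.assert_array_equal(flat, mip_b.signal)

    def test_3d_percentage_never_exceeds_flat(self):
        for seed in range(5):
            stack, truth = generate_stack(SyntheticSpec(seed=100 + seed), 3)
            _, p3d, pflat = stack_quantify(stack, truth.truth_mask)
            assert p3d <= pflat
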