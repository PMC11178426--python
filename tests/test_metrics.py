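"""SSIM, entropy, first-order statistics, and confusion-derived rates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis.extra.numpy import arrays
from skimage.metrics import structural_similarity

from tumnet import (
    ConfusionCounts,
    GrayImage,
    SSIMParams,
    ShapeMismatchError,
    UndefinedMetricError,
    accuracy,
    confusion,
    entropy,
    first_order_stats,
    fusion_report,
    sensitivity,
    specificity,
    ssim,
)
from tumnet.phantom import PhantomSpec, generate_phantom
from tumnet.segmentation import BinaryMask


class TestSSIM:
    def test_identical_images_score_one(self, rng):
        x = GrayImage(rng.integers(0, 256, (40, 40)).astype(float))
        assert ssim(x, x) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        x = rng.integers(0, 256, (40, 40)).astype(float)
        y = np.clip(x + rng.normal(0, 20, x.shape), 0, 255)
        assert ssim(x, y) == pytest.approx(ssim(y, x))

    def test_inverted_high_variance_image_scores_low(self, rng):
        x = rng.integers(0, 256, (64, 64)).astype(float)
        assert ssim(x, 255 - x) < 0.5

    def test_matches_independent_reference_implementation(self, rng):
        x = rng.integers(0, 256, (64, 64)).astype(float)
        y = np.clip(x + rng.normal(0, 30, x.shape), 0, 255)
        ref = structural_similarity(
            x, y, win_size=7, gaussian_weights=False,
            data_range=255, use_sample_covariance=False,
        )
        assert ssim(x, y) == pytest.approx(ref, abs=1e-12)

    def test_bounded_by_one_in_magnitude(self, rng):
        x = rng.integers(0, 256, (32, 32)).astype(float)
        for y in (255 - x, np.roll(x, 7, axis=0), np.zeros_like(x)):
            assert abs(ssim(x, y)) <= 1.0 + 1e-12

    def test_global_mode(self, rng):
        x = rng.integers(0, 256, (32, 32)).astype(float)
        params = SSIMParams(windowed=False)
        assert ssim(x, x, params) == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeMismatchError):
            ssim(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SSIMParams(k1=0)
        with pytest.raises(ValueError):
            SSIMParams(window=4)


class TestEntropy:
    def test_constant_image_zero_bits(self):
        assert entropy(GrayImage(np.full((16, 16), 99.0))) == 0.0

    def test_uniform_256_levels_eight_bits(self):
        img = np.arange(256.0).repeat(4).reshape(32, 32)
        assert entropy(GrayImage(img)) == pytest.approx(8.0)

    def test_two_equal_bins_one_bit(self):
        img = np.zeros((16, 16))
        img[:, 8:] = 255.0
        assert entropy(GrayImage(img)) == pytest.approx(1.0)

    @given(arrays(np.uint8, (12, 12)))
    @settings(max_examples=50, deadline=None)
    def test_bounded_zero_to_eight_bits(self, arr):
        e = entropy(GrayImage(arr.astype(float)))
        assert 0.0 <= e <= 8.0


class TestConfusionRates:
    def test_perfect_prediction(self):
        m = np.zeros((6, 6), bool)
        m[2:4, 2:4] = True
        c = confusion(m, m)
        assert c.FP == c.FN == 0
        assert accuracy(c) == 1.0 and sensitivity(c) == 1.0 and specificity(c) == 1.0

    def test_empty_prediction_counts_all_positives_as_misses(self):
        truth = np.zeros((4, 4), bool)
        truth[0, :3] = True
        c = confusion(np.zeros((4, 4), bool), truth)
        assert c.TP == 0 and c.FN == 3

    def test_complement_masks_share_no_hits(self):
        m = np.zeros((4, 4), bool)
        m[:2] = True
        c = confusion(m, ~m)
        assert c.TP == 0 and c.TN == 0
        assert accuracy(c) == 0.0

    def test_counts_partition_the_pixel_grid(self, rng):
        p = rng.random((9, 9)) > 0.5
        t = rng.random((9, 9)) > 0.3
        c = confusion(p, t)
        assert c.total == 81

    @pytest.mark.parametrize(
        "counts, sens, spec, acc",
        [
            (ConfusionCounts(TP=9, FP=0, TN=0, FN=1), 0.9, None, 0.9),
            (ConfusionCounts(TP=96, FP=1, TN=99, FN=4), 0.96, 0.99, 0.975),
            (ConfusionCounts(TP=45, FP=5, TN=45, FN=5), 0.9, 0.9, 0.9),
            (ConfusionCounts(TP=1, FP=7, TN=7, FN=0), 1.0, 0.5, 8 / 15),
        ],
    )
    def test_rates_match_hand_arithmetic(self, counts, sens, spec, acc):
        assert sensitivity(counts) == pytest.approx(sens)
        if spec is not None:
            assert specificity(counts) == pytest.approx(spec)
        assert accuracy(counts) == pytest.approx(acc)

    def test_zero_denominators_raise_not_return_zero(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity(ConfusionCounts(TP=0, FP=3, TN=5, FN=0))
        with pytest.raises(UndefinedMetricError):
            specificity(ConfusionCounts(TP=2, FP=0, TN=0, FN=1))
        with pytest.raises(UndefinedMetricError):
            accuracy(ConfusionCounts(TP=0, FP=0, TN=0, FN=0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(TP=-1, FP=0, TN=0, FN=0)


class TestFirstOrderStats:
    def test_constant_image(self):
        mean, std, var = first_order_stats(GrayImage(np.full((8, 8), 77.0)))
        assert (mean, std, var) == (77.0, 0.0, 0.0)

    def test_normalized_binary_image(self):
        img = np.zeros((10, 10))
        img[:5] = 255.0
        mean, std, var = first_order_stats(GrayImage(img), normalized=True)
        assert mean == pytest.approx(0.5)
        assert var == pytest.approx(0.25)
        assert std == pytest.approx(0.5)

    def test_variance_is_std_squared(self, rng):
        _, std, var = first_order_stats(rng.integers(0, 256, (12, 12)).astype(float))
        assert var == pytest.approx(std**2)


class TestFusionReport:
    def test_identical_inputs_give_unit_ssim(self, rng):
        x = GrayImage(rng.integers(0, 256, (32, 32)).astype(float))
        report = fusion_report(x, x, x)
        assert report.ssim_tissue == pytest.approx(1.0)
        assert report.ssim_bone == pytest.approx(1.0)

    def test_truth_omitted_leaves_confusion_fields_absent(self, rng):
        x = GrayImage(rng.integers(0, 256, (32, 32)).astype(float))
        report = fusion_report(x, x, x)
        assert report.sensitivity is None and report.accuracy is None
        assert report.entropy_bits > 0

    def test_average_fusion_is_closer_to_both_sources_than_they_are_to_each_other(self):
        sample = generate_phantom(PhantomSpec(rng_seed=21))
        fused = sample.fused("average")
        report = fusion_report(sample.mri_like, sample.ct_like, fused)
        cross = ssim(sample.mri_like, sample.ct_like)
        assert report.ssim_tissue > cross
        assert report.ssim_bone > cross

    def test_confusion_block_when_truth_supplied(self):
        pred = np.zeros((8, 8), bool)
        pred[2:5, 2:5] = True
        truth = np.zeros((8, 8), bool)
        truth[2:6, 2:5] = True
        img = GrayImage(np.where(pred, 200.0, 10.0))
        report = fusion_report(
            img, img, img,
            tumor_mask=BinaryMask(pred), truth_mask=BinaryMask(truth),
        )
        assert report.sensitivity == pytest.approx(9 / 12)
        assert report.accuracy is not None
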