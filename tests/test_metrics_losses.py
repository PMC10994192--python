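"""Losses and metrics: closed-form values, conventions, reference oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from umsrep.metrics_losses import (CombinedLossConfig, ConfusionCounts, MetricError,
                                   bce_loss, cce_loss, classification_metrics,
                                   combined_seg_loss, dice_coefficient, dice_loss,
                                   iou, mcnemar_test, ms_ssim, psnr, ssim)


class TestBCE:
    def test_perfect_prediction_is_zero(self):
        assert bce_loss(np.array([1.0]), np.array([1.0])) == pytest.approx(0.0, abs=2e-7)

    @pytest.mark.parametrize("t", [0.0, 1.0])
    def test_half_probability_costs_ln2(self, t):
        assert bce_loss(np.array([t]), np.array([0.5])) == pytest.approx(math.log(2))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(MetricError):
            bce_loss(np.zeros(3), np.zeros(4))


class TestDice:
    def test_identical_masks_cost_zero(self):
        ones = np.ones(7)
        assert dice_loss(ones, ones) == 0.0

    def test_disjoint_masks_cost_one(self):
        assert dice_loss(np.ones(4), np.zeros(4)) == 1.0

    def test_half_overlap_costs_one_third(self):
        assert dice_loss(np.array([1, 1, 1, 1.0]),
                         np.array([1, 1, 0, 0.0])) == pytest.approx(1 / 3)

    def test_empty_vs_empty_convention(self):
        assert dice_loss(np.zeros(5), np.zeros(5)) == 0.0


class TestCombined:
    def test_zero_weights_give_zero(self, rng):
        cfg = CombinedLossConfig(w1=0.0, w2=0.0)
        t = (rng.random(10) > 0.5).astype(float)
        assert combined_seg_loss(t, rng.random(10), cfg) == 0.0

    def test_worked_pair(self):
        t, y = np.array([1.0, 1.0]), np.array([0.5, 0.5])
        expected = 0.5 * math.log(2) + 0.5 * (1 - 2 * 1.0 / (2 + 1))
        assert combined_seg_loss(t, y) == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(0.5132, abs=1e-4)

    def test_compositional_identity(self, rng):
        t = (rng.random((8, 8)) > 0.5).astype(float)
        y = rng.random((8, 8))
        cfg = CombinedLossConfig(w1=0.3, w2=0.7)
        assert combined_seg_loss(t, y, cfg) == pytest.approx(
            0.3 * bce_loss(t, y) + 0.7 * dice_loss(t, y), rel=1e-9)

    @given(st.floats(0, 2), st.floats(0, 2))
    def test_linearity_in_weights(self, w1, w2):
        rng = np.random.default_rng(0)
        t = (rng.random(16) > 0.5).astype(float)
        y = rng.random(16)
        got = combined_seg_loss(t, y, CombinedLossConfig(w1=w1, w2=w2))
        assert got == pytest.approx(w1 * bce_loss(t, y) + w2 * dice_loss(t, y),
                                    rel=1e-9, abs=1e-12)


class TestCCE:
    def test_confident_correct_is_zero(self):
        assert cce_loss(np.array([0, 1.0, 0]),
                        np.array([0, 1.0, 0])) == pytest.approx(0.0, abs=2e-7)

    def test_uniform_three_way_costs_ln3(self):
        assert cce_loss(np.array([1.0, 0, 0]),
                        np.full(3, 1 / 3)) == pytest.approx(math.log(3))

    def test_wrong_class_grows_as_clamp_shrinks(self):
        t = np.array([1.0, 0.0])
        y = np.array([0.0, 1.0])
        assert cce_loss(t, y, epsilon=1e-3) < cce_loss(t, y, epsilon=1e-6)

    def test_non_distribution_rejected(self):
        with pytest.raises(MetricError):
            cce_loss(np.array([1.0, 0.0]), np.array([0.6, 0.6]))


class TestPSNR:
    def test_identical_images_hit_the_sentinel(self, rng):
        img = rng.random((8, 8))
        assert psnr(img, img) == float("inf")

    def test_unit_mse_on_255_range(self):
        ref = np.zeros((10, 10))
        test = np.ones((10, 10))
        assert psnr(ref, test, data_range=255.0) == pytest.approx(
            10 * math.log10(255 ** 2), abs=1e-4)   # 48.1308 dB

    def test_halving_data_range_costs_six_db(self, rng):
        ref, test = rng.random((8, 8)), rng.random((8, 8))
        drop = psnr(ref, test, 1.0) - psnr(ref, test, 0.5)
        assert drop == pytest.approx(20 * math.log10(2), abs=1e-9)

    def test_noise_monotonically_degrades_psnr(self):
        clean = np.full((64, 64), 0.5)
        values = []
        for sigma in (10, 20, 30, 40, 50):
            rng = np.random.default_rng(sigma)
            noisy = np.clip(clean + rng.normal(0, sigma / 255, clean.shape), 0, 1)
            values.append(psnr(clean, noisy))
        assert all(a > b for a, b in zip(values, values[1:]))


class TestSSIM:
    def test_identical_images_score_one(self, rng):
        img = rng.random((32, 32))
        assert ssim(img, img) == pytest.approx(1.0, abs=1e-9)
        assert ms_ssim(img, img, n_scales=2) == pytest.approx(1.0, abs=1e-9)

    def test_inverted_checkerboard_is_negative(self):
        board = np.indices((32, 32)).sum(axis=0) % 2.0
        assert ssim(board, 1.0 - board) < 0

    def test_matches_skimage_reference(self, rng):
        from skimage.metrics import structural_similarity

        for _ in range(5):
            a, b = rng.random((64, 64)), rng.random((64, 64))
            ref = structural_similarity(a, b, data_range=1.0, gaussian_weights=True,
                                        sigma=1.5, use_sample_covariance=False)
            assert ssim(a, b) == pytest.approx(ref, abs=1e-4)

    def test_too_small_for_pyramid_rejected(self, rng):
        img = rng.random((32, 32))
        with pytest.raises(MetricError):
            ms_ssim(img, img, n_scales=5)
        with pytest.raises(MetricError):
            ssim(rng.random((8, 8)), rng.random((8, 8)))

    def test_ms_ssim_penalizes_noise(self, rng):
        img = rng.random((64, 64))
        noisy = np.clip(img + rng.normal(0, 0.2, img.shape), 0, 1)
        assert ms_ssim(img, noisy, n_scales=2) < ms_ssim(img, img, n_scales=2)


class TestClassificationMetrics:
    def test_perfect_classifier(self):
        m = classification_metrics(ConfusionCounts(tp=5, fp=0, fn=0, tn=5))
        assert m == {"accuracy": 1.0, "f_score": 1.0, "mcc": 1.0}

    def test_worked_mcc(self):
        m = classification_metrics(ConfusionCounts(tp=4, fp=1, fn=1, tn=2))
        assert m["mcc"] == pytest.approx(7 / 15)

    def test_single_class_predictions_give_mcc_zero(self):
        m = classification_metrics(ConfusionCounts(tp=3, fp=0, fn=2, tn=0))
        assert m["mcc"] == 0.0

    def test_mcc_invariant_under_class_swap(self, rng):
        for _ in range(20):
            tp, fp, fn, tn = rng.integers(0, 30, 4)
            if tp + fp + fn + tn == 0:
                continue
            a = classification_metrics(ConfusionCounts(int(tp), int(fp), int(fn), int(tn)))
            b = classification_metrics(ConfusionCounts(int(tn), int(fn), int(fp), int(tp)))
            assert a["mcc"] == pytest.approx(b["mcc"], abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(MetricError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=1)


class TestIoU:
    def test_identical_masks(self):
        m = np.array([1, 0, 1])
        assert iou(m, m) == 1.0

    def test_disjoint_masks(self):
        assert iou(np.array([1, 0]), np.array([0, 1])) == 0.0

    def test_partial_overlap(self):
        assert iou(np.array([1, 1, 0, 0]), np.array([0, 1, 1, 0])) == pytest.approx(1 / 3)

    def test_empty_vs_empty_is_one(self):
        assert iou(np.zeros(4), np.zeros(4)) == 1.0

    def test_dice_iou_identity_on_random_masks(self, rng):
        for _ in range(200):
            a = rng.random(32) > 0.5
            b = rng.random(32) > 0.5
            j = iou(a, b)
            assert dice_coefficient(a, b) == pytest.approx(2 * j / (1 + j), abs=1e-12)


class TestMcNemar:
    def test_balanced_discordance_is_insignificant(self):
        assert mcnemar_test(5, 5) == pytest.approx(1.0)

    def test_one_sided_discordance_exact_value(self):
        assert mcnemar_test(10, 0) == pytest.approx(2 * 0.5 ** 10)

    def test_no_discordant_pairs(self):
        assert mcnemar_test(0, 0) == 1.0

    @pytest.mark.parametrize("b,c", [(3, 9), (1, 12), (7, 7), (0, 20)])
    def test_exact_branch_matches_statsmodels(self, b, c):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        table = [[0, b], [c, 0]]
        ref = sm_mcnemar(table, exact=True).pvalue
        assert mcnemar_test(b, c) == pytest.approx(ref, rel=1e-9)

    @pytest.mark.parametrize("b,c", [(20, 10), (40, 18), (13, 12)])
    def test_chi_square_branch_matches_statsmodels(self, b, c):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        table = [[0, b], [c, 0]]
        ref = sm_mcnemar(table, exact=False, correction=True).pvalue
        assert mcnemar_test(b, c) == pytest.approx(ref, rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(MetricError):
            mcnemar_test(-1, 2)
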