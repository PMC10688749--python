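"""Losses and evaluation metrics against hand-computed and algebraic oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellseg import (
    ConfusionCounts,
    LossConfig,
    combined_loss,
    confusion,
    dice_loss,
    dice_score,
    metrics_row,
    miou,
    precision,
    recall,
    weighted_cross_entropy,
)


class TestWeightedCrossEntropy:
    def test_hand_value_half_probability(self):
        # p=1, p_hat=0.5, beta=1 -> -ln(0.5)
        assert weighted_cross_entropy(np.array([0.5]), np.array([1.0])) == pytest.approx(
            math.log(2), rel=1e-9
        )

    def test_perfect_prediction_is_near_zero(self):
        p = np.array([1.0, 0.0, 1.0])
        assert weighted_cross_entropy(p, p) <= -math.log(1 - 1e-6) + 1e-12

    def test_beta_scales_positive_term_linearly(self):
        base = weighted_cross_entropy(np.array([0.5]), np.array([1.0]), beta=1.0)
        assert weighted_cross_entropy(
            np.array([0.5]), np.array([1.0]), beta=2.0
        ) == pytest.approx(2 * base)

    def test_matches_elementwise_oracle(self, rng):
        p_hat = rng.uniform(0.01, 0.99, size=(5, 7))
        p = (rng.uniform(size=(5, 7)) < 0.3).astype(float)
        beta = 1.7
        expected = -np.mean(
            beta * p * np.log(p_hat) + (1 - p) * np.log(1 - p_hat)
        )
        assert weighted_cross_entropy(p_hat, p, beta=beta) == pytest.approx(
            expected, rel=1e-6
        )

    def test_monotone_in_prediction(self):
        # non-increasing in p_hat at p=1, non-decreasing at p=0
        grid = np.linspace(0.05, 0.95, 19)
        at_one = [weighted_cross_entropy(np.array([q]), np.array([1.0])) for q in grid]
        at_zero = [weighted_cross_entropy(np.array([q]), np.array([0.0])) for q in grid]
        assert all(a >= b - 1e-12 for a, b in zip(at_one, at_one[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(at_zero, at_zero[1:]))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            weighted_cross_entropy(np.zeros(3), np.zeros(4))


class TestDiceLoss:
    def test_identical_binary_masks(self):
        m = np.array([1.0, 0, 1, 1])
        assert dice_loss(m, m) == pytest.approx(0.0, abs=1e-5)

    def test_disjoint_equal_area(self):
        a = np.array([1.0, 1, 0, 0])
        b = np.array([0.0, 0, 1, 1])
        assert dice_loss(a, b) == pytest.approx(1.0, abs=1e-5)

    def test_half_overlap_set_counting(self):
        # |X|=4, |Y|=4, |X n Y|=2 -> 1 - 4/8 = 0.5
        x = np.array([1.0, 1, 1, 1, 0, 0])
        y = np.array([1.0, 1, 0, 0, 1, 1])
        assert dice_loss(x, y, epsilon=1e-12) == pytest.approx(0.5, abs=1e-9)

    def test_complement_of_coefficient(self, rng):
        p_hat = rng.uniform(size=20)
        p = (rng.uniform(size=20) < 0.4).astype(float)
        eps = 1e-6
        coeff = (2 * np.sum(p_hat * p) + eps) / (np.sum(p_hat) + np.sum(p) + eps)
        assert dice_loss(p_hat, p, eps) + coeff == pytest.approx(1.0, rel=1e-9)


class TestCombinedLoss:
    def test_alpha_endpoints_and_midpoint(self, rng):
        p_hat = rng.uniform(0.01, 0.99, size=16)
        p = (rng.uniform(size=16) < 0.3).astype(float)
        wce = weighted_cross_entropy(p_hat, p)
        dsc = dice_loss(p_hat, p)
        assert combined_loss(p_hat, p, LossConfig(alpha=1.0)) == pytest.approx(wce)
        assert combined_loss(p_hat, p, LossConfig(alpha=0.0)) == pytest.approx(dsc)
        assert combined_loss(p_hat, p, LossConfig(alpha=0.5)) == pytest.approx(
            0.5 * (wce + dsc)
        )

    def test_worked_blend_value(self):
        # WCE = -ln 0.5 = 0.693147, Dice = 0.5 -> alpha=0.5 blend 0.596574
        p_hat = np.array([0.5])
        p = np.array([1.0])
        wce = weighted_cross_entropy(p_hat, p)
        dsc = 0.5
        assert 0.5 * wce + 0.5 * dsc == pytest.approx(0.596574, abs=5e-6)

    def test_affine_in_alpha(self, rng):
        p_hat = rng.uniform(0.01, 0.99, size=(4, 4))
        p = (rng.uniform(size=(4, 4)) < 0.5).astype(float)
        l0 = combined_loss(p_hat, p, LossConfig(alpha=0.0))
        l5 = combined_loss(p_hat, p, LossConfig(alpha=0.5))
        l1 = combined_loss(p_hat, p, LossConfig(alpha=1.0))
        assert l5 == pytest.approx(0.5 * (l0 + l1), rel=1e-9)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(alpha=1.5)


class TestConfusion:
    def test_four_pixel_enumeration(self):
        pred = np.array([[1, 0], [1, 0]])
        true = np.array([[1, 1], [0, 0]])
        c = confusion(pred, true)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_identical_masks_no_errors(self):
        m = np.array([[1, 0], [0, 1]])
        c = confusion(m, m)
        assert c.fp == 0 and c.fn == 0

    def test_all_background(self):
        z = np.zeros((3, 4), dtype=int)
        c = confusion(z, z)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 0, 12)

    def test_counts_sum_to_pixel_total(self, rng):
        pred = (rng.uniform(size=(9, 11)) < 0.5).astype(int)
        true = (rng.uniform(size=(9, 11)) < 0.5).astype(int)
        assert confusion(pred, true).total == 99

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            confusion(np.array([[2, 0]]), np.array([[1, 0]]))


class TestMetrics:
    def test_dice_hand_value(self):
        assert dice_score(ConfusionCounts(2, 2, 2, 0)) == pytest.approx(50.0)

    def test_perfect_and_empty_overlap(self):
        assert dice_score(ConfusionCounts(5, 0, 0, 5)) == 100.0
        assert dice_score(ConfusionCounts(0, 3, 2, 5)) == 0.0

    def test_miou_hand_value(self):
        assert miou(ConfusionCounts(3, 1, 2, 0)) == pytest.approx(50.0)
        assert miou(ConfusionCounts(4, 0, 0, 4)) == 100.0

    def test_precision_recall_hand_values(self):
        assert precision(ConfusionCounts(1, 1, 0, 0)) == pytest.approx(50.0)
        assert recall(ConfusionCounts(1, 0, 3, 0)) == pytest.approx(25.0)
        assert precision(ConfusionCounts(4, 0, 1, 0)) == 100.0

    def test_undefined_metrics_are_nan(self):
        assert math.isnan(precision(ConfusionCounts(0, 0, 5, 5)))
        assert math.isnan(recall(ConfusionCounts(0, 5, 0, 5)))

    def test_both_masks_empty_convention(self):
        assert dice_score(ConfusionCounts(0, 0, 0, 10)) == 100.0
        assert miou(ConfusionCounts(0, 0, 0, 10)) == 100.0

    @given(
        tp=st.integers(1, 10**6),
        fp=st.integers(0, 10**6),
        fn=st.integers(0, 10**6),
    )
    @settings(max_examples=200, deadline=None)
    def test_dice_is_harmonic_mean_and_f1(self, tp, fp, fn):
        c = ConfusionCounts(tp, fp, fn, 0)
        p, r = precision(c), recall(c)
        f1 = 2 * p * r / (p + r)
        assert dice_score(c) == pytest.approx(f1, rel=1e-9)

    @given(
        tp=st.integers(0, 1000),
        fp=st.integers(0, 1000),
        fn=st.integers(0, 1000),
        tn=st.integers(0, 1000),
    )
    @settings(max_examples=200, deadline=None)
    def test_metrics_bounded_and_dice_dominates_iou(self, tp, fp, fn, tn):
        c = ConfusionCounts(tp, fp, fn, tn)
        row = metrics_row(c)
        for v in row.values():
            assert math.isnan(v) or 0.0 <= v <= 100.0
        if tp > 0:
            assert dice_score(c) >= miou(c)
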