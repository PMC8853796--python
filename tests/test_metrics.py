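"""Pixel-metric correctness against brute-force oracles."""

import numpy as np
import pytest

from psobsa import metrics as em
from psobsa.synthdata import PSORIASIS


def brute_force_counts(pred, true, positive_class):
    """Per-pixel python-loop tally, independent of the vectorised path."""
    tp = fp = fn = tn = 0
    for p, t in zip(pred.reshape(-1), true.reshape(-1)):
        if p == positive_class and t == positive_class:
            tp += 1
        elif p == positive_class:
            fp += 1
        elif t == positive_class:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def brute_force_metrics(pred, true, positive_class=PSORIASIS):
    tp, fp, fn, tn = brute_force_counts(pred, true, positive_class)
    nan = float("nan")
    acc = sum(int(p == t) for p, t in zip(pred.reshape(-1),
                                          true.reshape(-1))) / pred.size
    ji = tp / (tp + fp + fn) if tp + fp + fn else nan
    dsc = 2 * tp / (2 * tp + fn + fp) if 2 * tp + fn + fp else nan
    se = tp / (tp + fn) if tp + fn else nan
    sp = tn / (tn + fp) if tn + fp else nan
    return acc, ji, dsc, se, sp


class TestConfusionCounts:
    def test_perfect_prediction_has_no_errors(self):
        mask = np.array([[0, 1], [2, 2]])
        c = em.confusion_counts(mask, mask, positive_class=2)
        assert c.fp == c.fn == 0 and c.tp == 2 and c.tn == 2

    def test_absent_class_counts_all_negative(self):
        mask = np.zeros((4, 4), dtype=int)
        c = em.confusion_counts(mask, mask, positive_class=2)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 0, 16)

    def test_hand_enumerated_4x4(self):
        rng = np.random.default_rng(5)
        pred = rng.integers(0, 3, (4, 4))
        true = rng.integers(0, 3, (4, 4))
        c = em.confusion_counts(pred, true, positive_class=2)
        assert (c.tp, c.fp, c.fn, c.tn) == brute_force_counts(pred, true, 2)
        assert c.total == 16

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            em.confusion_counts(np.zeros((2, 2)), np.zeros((3, 3)))


class TestSegmentationMetrics:
    def test_direct_arithmetic_example(self):
        # TP=1, FP=1, FN=2, TN=0 on a 2x2 grid
        pred = np.array([[2, 2], [0, 0]])
        true = np.array([[2, 0], [2, 2]])
        r = em.segmentation_metrics(pred, true)
        assert r.ji == pytest.approx(0.25)
        assert r.dsc == pytest.approx(0.4)

    def test_perfect_prediction_all_ones(self):
        rng = np.random.default_rng(0)
        mask = rng.integers(0, 3, (8, 8))
        r = em.segmentation_metrics(mask, mask)
        assert (r.acc, r.ji, r.dsc, r.se, r.sp) == (1, 1, 1, 1, 1)

    def test_undefined_when_class_absent(self):
        pred = np.zeros((4, 4), dtype=int)
        true = np.zeros((4, 4), dtype=int)
        r = em.segmentation_metrics(pred, true)
        assert np.isnan(r.ji) and np.isnan(r.dsc) and np.isnan(r.se)
        assert r.sp == 1.0 and r.acc == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.integers(0, 3, (8, 8))
        true = rng.integers(0, 3, (8, 8))
        r = em.segmentation_metrics(pred, true)
        for got, want in zip((r.acc, r.ji, r.dsc, r.se, r.sp),
                             brute_force_metrics(pred, true)):
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_dice_jaccard_identity_and_order(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            pred = rng.integers(0, 3, (6, 6))
            true = rng.integers(0, 3, (6, 6))
            r = em.segmentation_metrics(pred, true)
            if not np.isnan(r.ji):
                assert r.dsc == pytest.approx(2 * r.ji / (1 + r.ji), abs=1e-12)
                assert r.ji <= r.dsc + 1e-15

    def test_swapping_masks_preserves_dice(self):
        rng = np.random.default_rng(3)
        pred = rng.integers(0, 3, (8, 8))
        true = rng.integers(0, 3, (8, 8))
        r1 = em.segmentation_metrics(pred, true)
        r2 = em.segmentation_metrics(true, pred)
        c1 = em.confusion_counts(pred, true)
        c2 = em.confusion_counts(true, pred)
        assert (c1.fp, c1.fn) == (c2.fn, c2.fp)
        assert r1.dsc == pytest.approx(r2.dsc, nan_ok=True)
        assert r1.ji == pytest.approx(r2.ji, nan_ok=True)

    def test_binary_accuracy_flag(self):
        pred = np.array([[2, 1], [0, 0]])
        true = np.array([[2, 0], [1, 0]])
        r = em.segmentation_metrics(pred, true, binary_accuracy=True)
        # one-vs-rest for class 2: TP=1, TN=3
        assert r.acc == pytest.approx(1.0)


class TestRatios:
    def test_ratio_simple_counts(self):
        mask = np.concatenate([np.full(30, 2), np.full(70, 1),
                               np.zeros(900, dtype=int)]).reshape(10, 100)
        assert em.psoriasis_ratio(mask) == pytest.approx(0.30)

    def test_ratio_zero_without_lesions(self):
        mask = np.ones((5, 5), dtype=int)
        assert em.psoriasis_ratio(mask) == 0.0

    def test_ratio_undefined_without_body(self):
        assert np.isnan(em.psoriasis_ratio(np.zeros((4, 4), dtype=int)))

    def test_residual_absolute_difference(self):
        assert em.residual(0.30, 0.25) == pytest.approx(0.05)
        assert em.residual(0.4, 0.4) == 0.0
        rng = np.random.default_rng(2)
        for _ in range(100):
            a, b = rng.random(2)
            assert em.residual(a, b) == pytest.approx(abs(a - b), abs=1e-15)

    def test_residual_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            em.residual(1.2, 0.5)


class TestSummarize:
    def test_undefined_entries_lower_the_count(self):
        values = [0.5] * 47 + [float("nan")] * 2
        table = em.summarize(values)
        assert table.count == 47

    def test_even_length_median_interpolated(self):
        t = em.summarize([1, 2, 3, 4])
        assert t.q2 == pytest.approx(2.5)

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(7)
        vals = rng.random(500)
        t = em.summarize(vals)
        s = np.sort(vals)

        def interp_q(q):
            pos = q * (len(s) - 1)
            lo, frac = int(pos), pos - int(pos)
            return s[lo] * (1 - frac) + s[min(lo + 1, len(s) - 1)] * frac

        assert t.count == 500
        assert t.mean == pytest.approx(s.mean(), abs=1e-12)
        assert t.std == pytest.approx(np.std(vals, ddof=1), abs=1e-12)
        assert t.min == s[0] and t.max == s[-1]
        for got, q in ((t.q1, 0.25), (t.q2, 0.5), (t.q3, 0.75)):
            assert got == pytest.approx(interp_q(q), abs=1e-9)
        assert t.min <= t.q1 <= t.q2 <= t.q3 <= t.max

    def test_all_undefined_is_an_error(self):
        with pytest.raises(ValueError):
            em.summarize([float("nan")])
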