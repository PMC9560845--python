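"""Metric formulas against brute-force pixel-loop and pair-counting oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhanet.metrics import (
    ConfusionCounts,
    auc_score,
    confusion_counts,
    dice,
    iou_bg,
    iou_poly,
    metric_report,
    micro_report,
)


def pixel_loop_counts(pred, truth):
    """Naive per-pixel tally; the independent oracle."""
    tp = fp = tn = fn = 0
    for p, t in zip(pred.ravel().tolist(), truth.ravel().tolist()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def mann_whitney_auc(prob, truth):
    """Pair-enumeration AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    p = prob.ravel()
    t = truth.ravel().astype(bool)
    pos, neg = p[t], p[~t]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


TOY = ConfusionCounts(tp=3, fp=1, tn=94, fn=2)


class TestToyExamples:
    def test_counts_from_10x10_toy(self):
        truth = np.zeros((10, 10), dtype=np.uint8)
        truth.ravel()[:5] = 1  # 5 true pixels
        pred = np.zeros((10, 10), dtype=np.uint8)
        pred.ravel()[:3] = 1  # covers 3 of them
        pred.ravel()[7] = 1  # plus 1 background pixel
        c = confusion_counts(pred, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (3, 1, 2, 94)

    def test_dice_and_iou_on_toy_counts(self):
        assert dice(TOY) == pytest.approx(6 / 9)
        assert iou_poly(TOY) == pytest.approx(0.5)

    def test_report_fields_on_toy_counts(self):
        truth = np.zeros(100, dtype=np.uint8)
        truth[:5] = 1
        prob = np.zeros(100)
        prob[:3] = 0.9
        prob[7] = 0.9
        rep = metric_report(prob, truth)
        assert rep.rec == pytest.approx(0.6)
        assert rep.se == rep.rec
        assert rep.spec == pytest.approx(94 / 95)
        assert rep.prec == pytest.approx(0.75)
        assert rep.ioub == pytest.approx(94 / 97)
        assert rep.ac == pytest.approx(0.97)
        assert rep.ir == rep.ioup

    def test_auc_four_pixel_toy(self):
        assert auc_score(np.array([0.9, 0.6, 0.4, 0.1]), np.array([1, 0, 1, 0])) == pytest.approx(0.75)


class TestIdentitiesAndEdgeCases:
    def test_identical_masks(self):
        m = (np.random.default_rng(0).random((8, 8)) > 0.5).astype(np.uint8)
        c = confusion_counts(m, m)
        assert c.fp == c.fn == 0
        assert dice(c) == iou_poly(c) == 1.0

    def test_complement_masks(self):
        m = (np.random.default_rng(1).random((8, 8)) > 0.5).astype(np.uint8)
        c = confusion_counts(1 - m, m)
        assert c.tp == c.tn == 0
        assert dice(c) == 0.0

    def test_empty_vs_empty_scores_one_with_warning(self):
        z = np.zeros((4, 4), dtype=np.uint8)
        with pytest.warns(UserWarning, match="degenerate"):
            assert dice(confusion_counts(z, z)) == 1.0

    def test_shape_mismatch_and_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            confusion_counts(np.zeros((2, 2)), np.zeros((2, 3)))
        with pytest.raises(ValueError, match="binary"):
            confusion_counts(np.array([0, 2]), np.array([0, 1]))

    def test_probabilities_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            metric_report(np.array([1.5, 0.0]), np.array([1, 0]))

    def test_auc_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            auc_score(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_constant_probabilities_give_chance_auc(self):
        t = np.array([1, 0, 1, 0, 0])
        assert auc_score(np.full(5, 0.3), t) == pytest.approx(0.5)

    def test_perfect_predictor_scores_one_everywhere(self):
        truth = (np.random.default_rng(2).random((6, 6)) > 0.6).astype(np.uint8)
        rep = metric_report(truth.astype(float), truth)
        for field in ("dc", "ir", "rec", "spec", "prec", "ioup", "ioub", "miou", "ac", "auc"):
            assert getattr(rep, field) == pytest.approx(1.0), field


def test_random_pairs_match_pixel_loop_oracle():
    """200 random mask pairs: every metric equals the naive loop to 1e-12."""
    rng = np.random.default_rng(3)
    for _ in range(200):
        h, w = rng.integers(2, 33, size=2)
        density = rng.uniform(0.1, 0.9)
        truth = (rng.random((h, w)) < density).astype(np.uint8)
        prob = rng.random((h, w))
        pred = (prob >= 0.5).astype(np.uint8)
        tp, fp, tn, fn = pixel_loop_counts(pred, truth)
        c = confusion_counts(pred, truth)
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)
        if tp + fp + fn:
            assert dice(c) == pytest.approx(2 * tp / (2 * tp + fp + fn), abs=1e-12)
            assert iou_poly(c) == pytest.approx(tp / (tp + fp + fn), abs=1e-12)
            # Dice-Jaccard identity
            assert dice(c) == pytest.approx(2 * iou_poly(c) / (1 + iou_poly(c)), abs=1e-12)
        if tn + fp + fn:
            assert iou_bg(c) == pytest.approx(tn / (tn + fp + fn), abs=1e-12)
        rep = metric_report(prob, truth)
        assert rep.miou == pytest.approx((rep.ioup + rep.ioub) / 2, abs=1e-12)
        if truth.any() and not truth.all():
            assert rep.auc == pytest.approx(mann_whitney_auc(prob, truth), abs=1e-12)
        # symmetry of Dice; rec/prec swap under argument exchange
        c_sw = confusion_counts(truth, pred)
        assert dice(c_sw) == pytest.approx(dice(c), abs=1e-12)
        assert (c_sw.tp, c_sw.fp, c_sw.fn) == (c.tp, c.fn, c.fp)


@settings(max_examples=50, derandomize=True)
@given(
    tp=st.integers(0, 500), fp=st.integers(0, 500), tn=st.integers(0, 500), fn=st.integers(0, 500)
)
def test_dice_jaccard_identity_on_arbitrary_counts(tp, fp, tn, fn):
    import warnings

    c = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate counts warn by design
        d, j = dice(c), iou_poly(c)
    assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)


def test_micro_average_pools_pixels():
    rng = np.random.default_rng(4)
    probs = [rng.random((5, 5)) for _ in range(3)]
    truths = [(rng.random((5, 5)) > 0.5).astype(np.uint8) for _ in range(3)]
    rep = micro_report(probs, truths)
    pooled = metric_report(
        np.concatenate([p.ravel() for p in probs]),
        np.concatenate([t.ravel() for t in truths]),
    )
    assert rep == pooled
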