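"""Confusion counts, scalar metrics, PR/ROC machinery and the
equilibrium-point binarization, checked against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lighteyes.metrics import (
    ConfusionCounts,
    confusion,
    equilibrium_threshold,
    evaluate_maps,
    ji_from_pr_re,
    roc_auc,
    scalar_metrics,
)

from oracles import auc_mann_whitney, confusion_loop, equilibrium_exhaustive


class TestConfusion:
    def test_perfect_prediction(self):
        gt = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        c = confusion(gt, gt)
        assert (c.tp, c.tn, c.fp, c.fn) == (3, 7, 0, 0)

    def test_fov_excludes_pixels_entirely(self):
        pred = np.ones((3, 3))
        gt = np.zeros((3, 3))
        fov = np.zeros((3, 3))
        fov[0, :2] = fov[1, :2] = 1  # 4 pixels in view
        c = confusion(pred, gt, fov)
        assert (c.fp, c.tp, c.fn, c.tn) == (4, 0, 0, 0)
        assert c.total == 4

    def test_matches_per_pixel_loop_oracle(self, rng):
        pred = rng.random((16, 16)) < 0.5
        gt = rng.random((16, 16)) < 0.3
        fov = rng.random((16, 16)) < 0.8
        c = confusion(pred, gt, fov)
        assert (c.tp, c.fp, c.fn, c.tn) == confusion_loop(pred, gt, fov)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((2, 2)), np.zeros((3, 3)))


class TestScalarMetrics:
    def test_direct_arithmetic_case(self):
        rep = scalar_metrics(ConfusionCounts(tp=3, fp=1, fn=1, tn=5))
        assert rep.pr == 0.75
        assert rep.se == 0.75
        assert rep.acc == 0.8
        assert rep.ji == 0.6

    def test_perfect_counts_give_unit_scores(self):
        rep = scalar_metrics(ConfusionCounts(tp=5, fp=0, fn=0, tn=5))
        assert rep.f1 == rep.ji == rep.pr == rep.se == 1.0

    def test_published_f1_identity(self):
        """F1 of the microaneurysm operating point Pr=0.4960, Re=0.4936 is
        0.4948 (harmonic mean, inputs rounded to 4 decimals)."""
        pr, re = 0.4960, 0.4936
        f1 = 2 * pr * re / (pr + re)
        assert abs(f1 - 0.4948) < 0.0005

    def test_zero_denominator_warns_and_returns_nan(self):
        with pytest.warns(UserWarning):
            rep = scalar_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=4))
        assert np.isnan(rep.pr)


class TestJaccardFromPrRe:
    @pytest.mark.parametrize(
        "pr,re,expected",
        [(0.4960, 0.4936, 0.3287), (0.7940, 0.7933, 0.6579), (1.0, 1.0, 1.0)],
    )
    def test_identity_values(self, pr, re, expected):
        assert abs(ji_from_pr_re(pr, re) - expected) < 0.0005

    def test_consistent_with_counts(self, rng):
        """JI from (Pr, Re) equals JI from any counts realising them."""
        tp, fp, fn = 37, 13, 21
        rep = scalar_metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=100))
        assert abs(ji_from_pr_re(rep.pr, rep.se) - rep.ji) < 1e-12

    def test_rejects_zero(self):
        with pytest.raises(ValueError):
            ji_from_pr_re(0.0, 0.5)


@given(
    tp=st.integers(0, 500),
    fp=st.integers(0, 500),
    fn=st.integers(0, 500),
)
@settings(derandomize=True, max_examples=200)
def test_jaccard_never_exceeds_f1(tp, fp, fn):
    """JI = F1/(2-F1) <= F1, equality only at 0 and 1."""
    if tp + fp + fn == 0:
        return
    rep = scalar_metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=10))
    assert rep.ji <= rep.f1 + 1e-12
    assert abs(rep.ji - rep.f1 / (2 - rep.f1)) < 1e-12
    if 0.0 < rep.f1 < 1.0:
        assert rep.ji < rep.f1


class TestEquilibrium:
    def test_binary_probabilities_give_unit_pr_re(self):
        gt = np.array([1, 1, 0, 0, 0])
        thr, binarized = equilibrium_threshold(gt.astype(float), gt)
        assert 0.0 < thr <= 1.0
        assert np.array_equal(binarized, gt)

    def test_six_pixel_toy_matches_exhaustive_sweep(self):
        gt = np.array([1, 1, 1, 0, 0, 0])
        p = np.array([0.9, 0.8, 0.4, 0.6, 0.3, 0.1])
        thr, binarized = equilibrium_threshold(p, gt)
        assert 0.4 < thr <= 0.6
        c = confusion(binarized, gt)
        assert c.tp / (c.tp + c.fp) == pytest.approx(2 / 3)
        assert c.tp / (c.tp + c.fn) == pytest.approx(2 / 3)
        t_oracle, gap_oracle = equilibrium_exhaustive(p, gt)
        assert gap_oracle == pytest.approx(0.0)

    def test_gap_is_global_minimum_over_grid(self, rng):
        p = rng.random(200)
        gt = (rng.random(200) < 0.3).astype(np.uint8)
        thr, binarized = equilibrium_threshold(p, gt)
        c = confusion(binarized, gt)
        gap = abs(c.tp / (c.tp + c.fp) - c.tp / (c.tp + c.fn))
        _, gap_oracle = equilibrium_exhaustive(p, gt)
        assert gap <= gap_oracle + 1e-12

    def test_no_foreground_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_threshold(np.array([0.2, 0.4]), np.array([0, 0]))


class TestRocAuc:
    def test_perfect_separation(self):
        gt = np.array([0, 0, 0, 1, 1])
        p = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        assert roc_auc(p, gt) == 1.0

    def test_uninformative_scores(self):
        gt = np.array([0, 1, 0, 1])
        p = np.full(4, 0.5)
        assert roc_auc(p, gt) == 0.5

    def test_matches_mann_whitney_oracle(self, rng):
        p = rng.random(20)
        gt = (rng.random(20) < 0.4).astype(np.uint8)
        if gt.sum() in (0, 20):
            gt[:2] = [0, 1]
        assert roc_auc(p, gt) == pytest.approx(auc_mann_whitney(p, gt))

    def test_invariant_under_monotone_transform(self, rng):
        p = rng.random(100)
        gt = (rng.random(100) < 0.3).astype(np.uint8)
        squashed = 1 / (1 + np.exp(-(3 * p - 1)))
        assert roc_auc(p, gt) == pytest.approx(roc_auc(squashed, gt))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))


def test_metrics_invariant_to_out_of_fov_pixels(rng):
    """Scrambling predictions outside the FOV changes nothing."""
    p = rng.random((20, 20))
    gt = (rng.random((20, 20)) < 0.3).astype(np.uint8)
    fov = np.zeros((20, 20), dtype=np.uint8)
    fov[4:16, 4:16] = 1
    pred = (p > 0.5).astype(np.uint8)
    scrambled = pred.copy()
    scrambled[fov == 0] = 1 - scrambled[fov == 0]
    a = scalar_metrics(confusion(pred, gt, fov))
    b = scalar_metrics(confusion(scrambled, gt, fov))
    assert a.to_dict() == b.to_dict()
    assert roc_auc(p, gt, fov) == roc_auc(np.where(fov, p, 1 - p), gt, fov)


def test_dataset_level_evaluation_pools_pixels(rng):
    """evaluate_maps concatenates images and picks one global threshold."""
    gts = [(rng.random((12, 12)) < 0.25).astype(np.uint8) for _ in range(3)]
    probs = [np.clip(g * 0.8 + rng.normal(0, 0.05, g.shape), 0, 1) for g in gts]
    report = evaluate_maps(probs, gts)
    assert report.auc > 0.95
    assert report.f1 > 0.8
    assert 0.0 < report.threshold < 1.0
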