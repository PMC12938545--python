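"""Dice, lesion matching, stratified summaries, paired comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from plugforge.errors import DataError
from plugforge.evaluation import (
    dice,
    match_lesions,
    paired_compare,
    stratify_and_summarize,
)


def _rand_blobs(rng, shape=(12, 12, 12), n_max=4):
    """Random instance-labelled volume with up to n_max box-shaped lesions."""
    vol = np.zeros(shape, dtype=int)
    for lid in range(1, rng.integers(0, n_max + 1) + 1):
        c = rng.integers(0, np.asarray(shape) - 3)
        size = rng.integers(1, 4, size=3)
        sl = tuple(slice(c[i], c[i] + size[i]) for i in range(3))
        vol[sl] = lid
    return vol


def brute_force_match(pred_labels, gt_labels):
    """Oracle: pairwise overlap enumeration over all (gt, pred) label pairs."""
    gt_ids = [g for g in np.unique(gt_labels) if g > 0]
    pred_ids = [p for p in np.unique(pred_labels) if p > 0]
    tp = sum(
        1 for g in gt_ids
        if any(np.any((gt_labels == g) & (pred_labels == p)) for p in pred_ids)
    )
    fp = sum(
        1 for p in pred_ids
        if not any(np.any((gt_labels == g) & (pred_labels == p)) for g in gt_ids)
    )
    return tp, len(gt_ids) - tp, fp


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[0, 0, 0] = True
        b[4, 4, 4] = True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, :4] = a[0, 1, :4] = True      # |A| = 8
        b[0, 1, :4] = b[0, 2, :4] = True      # |B| = 8, overlap 4
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty_convention(self):
        z = np.zeros((3, 3, 3), bool)
        assert dice(z, z) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(DataError):
            dice(np.zeros((3, 3, 3), bool), np.zeros((4, 4, 4), bool))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((6, 6, 6)) > 0.7
        b = rng.random((6, 6, 6)) > 0.7
        assert dice(a, b) == dice(b, a)
        assert 0.0 <= dice(a, b) <= 1.0


class TestMatchLesions:
    def test_partial_detection(self):
        gt = np.zeros((10, 10, 10), int)
        gt[1:3, 1:3, 1:3] = 1
        gt[7:9, 7:9, 7:9] = 2
        pred = np.zeros_like(gt)
        pred[2, 2, 2] = 1  # overlaps lesion 1 only
        m = match_lesions(pred, gt)
        assert (m.tp, m.fn, m.fp) == (1, 1, 0)

    def test_single_voxel_overlap_counts(self):
        gt = np.zeros((8, 8, 8), int)
        gt[2:5, 2:5, 2:5] = 1
        pred = np.zeros_like(gt)
        pred[4:7, 4:7, 4:7] = 1  # touches gt at exactly voxel (4,4,4)
        assert np.count_nonzero((gt > 0) & (pred > 0)) == 1
        m = match_lesions(pred, gt)
        assert (m.tp, m.fp) == (1, 0)

    def test_empty_prediction(self):
        gt = _rand_blobs(np.random.default_rng(0))
        m = match_lesions(np.zeros_like(gt), gt)
        assert m.tp == 0 and m.fp == 0 and m.fn == len(m.gt_ids)

    def test_one_prediction_covering_two_gt(self):
        gt = np.zeros((10, 10, 10), int)
        gt[1:3, 1:3, 1:3] = 1
        gt[5:7, 1:3, 1:3] = 2
        pred = np.zeros_like(gt)
        pred[0:8, 1:3, 1:3] = 1  # single component spanning both
        m = match_lesions(pred, gt)
        assert (m.tp, m.fn, m.fp) == (2, 0, 0)

    def test_grid_mismatch(self):
        with pytest.raises(DataError):
            match_lesions(np.zeros((3, 3, 3)), np.zeros((4, 4, 4)))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_agrees_with_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        gt = _rand_blobs(rng) > 0    # binary in, 26-connectivity instancing inside
        pred = _rand_blobs(rng) > 0
        m = match_lesions(pred, gt)
        assert m.tp + m.fn == len(m.gt_ids)
        assert (m.tp, m.fn, m.fp) == brute_force_match(_relabel(pred), _relabel(gt))


def _relabel(vol):
    from skimage import measure

    return measure.label(vol > 0, connectivity=3)


class TestStratifySummarize:
    def _match_from_counts(self, gt_n, tp_ids):
        """Minimal LesionMatchResult stand-in built through match_lesions on
        a synthetic 1-D arrangement."""
        gt = np.zeros((4 * gt_n + 4, 3, 3), int)
        pred = np.zeros_like(gt)
        for g in range(1, gt_n + 1):
            gt[4 * g:4 * g + 2, 1, 1] = g
            if g in tp_ids:
                pred[4 * g, 1, 1] = 1
        return match_lesions(pred, gt), gt

    def test_sensitivity_and_fp_rate_arithmetic(self):
        m, _ = self._match_from_counts(8, {1, 2, 3, 4, 5, 6})
        report = stratify_and_summarize([m], [{g: 2.0 for g in range(1, 9)}])
        assert report.overall["tp"] == 6
        assert report.overall["sensitivity"] == pytest.approx(6 / 8)

    def test_bin_totals_sum_to_overall(self):
        m, _ = self._match_from_counts(6, {1, 4, 5})
        lengths = {1: 1.0, 2: 2.5, 3: 4.0, 4: 7.0, 5: 20.0, 6: 14.9}
        report = stratify_and_summarize([m], [lengths])
        assert sum(b["gt"] for b in report.per_bin.values()) == report.overall["gt"]
        assert sum(b["tp"] for b in report.per_bin.values()) == report.overall["tp"]
        assert report.per_bin["[15,inf)"]["gt"] == 1

    def test_all_detected_gives_unit_sensitivity_with_unit_ci(self):
        m, _ = self._match_from_counts(5, {1, 2, 3, 4, 5})
        report = stratify_and_summarize([m], [{g: 4.0 for g in range(1, 6)}])
        assert report.overall["sensitivity"] == 1.0
        assert report.overall["ci95"][1] == pytest.approx(1.0)

    def test_no_gt_flags_undefined_sensitivity(self):
        m = match_lesions(np.zeros((4, 4, 4)), np.zeros((4, 4, 4)))
        report = stratify_and_summarize([m], [{}])
        assert not report.sensitivity_defined
        assert report.overall["sensitivity"] is None

    def test_wilson_ci_coverage(self):
        """Exact coverage of the 95 % Wilson interval stays >= 93 % for the
        proportions and sample sizes in play (summed over the binomial pmf,
        no Monte Carlo noise)."""
        from scipy.stats import binom
        from statsmodels.stats.proportion import proportion_confint

        for p in (0.7, 0.85, 0.95):
            for n in (100, 1600):
                k = np.arange(n + 1)
                lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
                coverage = float(np.sum(((lo <= p) & (p <= hi)) * binom.pmf(k, n, p)))
                assert coverage >= 0.93


class TestPairedCompare:
    def test_identical_vectors_conventional_p1(self):
        r = paired_compare(np.ones(10), np.ones(10))
        assert r.degenerate == "zero-variance"
        assert r.p == 1.0 and r.t == 0.0

    def test_constant_shift_flagged_degenerate(self):
        a = np.linspace(0, 1, 10)
        r = paired_compare(a + 0.1, a)
        assert r.degenerate == "zero-variance"
        assert r.p == 0.0 and r.mean_difference == pytest.approx(0.1)

    def test_insufficient_n(self):
        r = paired_compare(np.array([1.0]), np.array([2.0]))
        assert r.degenerate == "insufficient-n"

    def test_matches_scipy_on_regular_data(self, rng):
        a = rng.normal(size=30)
        b = a + rng.normal(0.3, 1.0, size=30)
        r = paired_compare(a, b)
        t, p = sps.ttest_rel(a, b)
        assert r.t == pytest.approx(float(t))
        assert r.p == pytest.approx(float(p))
        assert r.dof == 29
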