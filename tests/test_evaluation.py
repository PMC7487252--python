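from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stomadetect.calibration import StomaAnnotation
from stomadetect.detection import DEFAULT_TAU_GRID, DetectionConfig, WindowOracle
from stomadetect.evaluation import (count_accuracy, f_iso_levels,
                                    fit_counts_regression, match_detections,
                                    pr_curve, precision_recall_f)
from stomadetect.patches import PatchConfig


def exhaustive_best_matching(dets, truths, radius):
    """Maximum one-to-one matching within radius by brute-force enumeration
    (largest pair count; among those, smallest total distance)."""
    best = (0, 0.0)
    for k in range(min(len(dets), len(truths)), -1, -1):
        found = None
        for d_idx in permutations(range(len(dets)), k):
            for t_idx in permutations(range(len(truths)), k):
                dist = [np.hypot(dets[i][0] - truths[j][0],
                                 dets[i][1] - truths[j][1])
                        for i, j in zip(d_idx, t_idx)]
                if all(d <= radius for d in dist):
                    tot = sum(dist)
                    if found is None or tot < found:
                        found = tot
        if found is not None:
            return k, found
    return best


class TestMatching:
    def test_perfect_detector(self):
        truth = [StomaAnnotation("i", 10.0, 10.0), StomaAnnotation("i", 200.0, 50.0)]
        mr = match_detections(np.array([(10, 10), (200, 50)], float), truth)
        assert (mr.tp, mr.fp, mr.fn) == (2, 0, 0)

    def test_null_detector(self):
        truth = [StomaAnnotation("i", float(x), 5.0) for x in range(5)]
        mr = match_detections(np.empty((0, 2)), truth)
        assert (mr.tp, mr.fp, mr.fn) == (0, 0, 5)

    def test_greedy_prefers_nearest(self):
        mr = match_detections(np.array([(0, 0), (8, 0)], float),
                              np.array([(1, 0)], float), radius_px=60)
        assert (mr.tp, mr.fp, mr.fn) == (1, 1, 0)
        assert mr.pairs[0][2] == pytest.approx(1.0)

    def test_beyond_radius_unmatched(self):
        mr = match_detections(np.array([(0, 0)], float),
                              np.array([(100, 0)], float), radius_px=60)
        assert (mr.tp, mr.fp, mr.fn) == (0, 1, 1)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            match_detections(np.empty((0, 2)), [], radius_px=-1)

    @pytest.mark.parametrize("method", ["greedy", "hungarian"])
    def test_small_instances_match_exhaustive_tp(self, method):
        """On instances of <= 4 points both strategies find the maximum
        number of pairs (they can differ in which pairs)."""
        rng = np.random.default_rng(17)
        for _ in range(40):
            nd, nt = rng.integers(0, 5), rng.integers(0, 5)
            dets = rng.uniform(0, 150, size=(nd, 2))
            truths = rng.uniform(0, 150, size=(nt, 2))
            mr = match_detections(dets, truths, radius_px=60, method=method)
            k, _ = exhaustive_best_matching(dets.tolist(), truths.tolist(), 60)
            if method == "hungarian":
                assert mr.tp == k
            else:
                assert mr.tp <= k  # greedy is a valid (maximal) matching
                assert mr.fp == nd - mr.tp and mr.fn == nt - mr.tp
            for _, _, d in mr.pairs:
                assert d <= 60

    def test_one_to_one_invariant(self):
        rng = np.random.default_rng(3)
        dets = rng.uniform(0, 100, (6, 2))
        truths = rng.uniform(0, 100, (4, 2))
        mr = match_detections(dets, truths, radius_px=80)
        d_idx = [p[0] for p in mr.pairs]
        t_idx = [p[1] for p in mr.pairs]
        assert len(set(d_idx)) == len(d_idx) and len(set(t_idx)) == len(t_idx)
        assert mr.tp == len(mr.pairs)
        assert mr.fp == len(dets) - mr.tp and mr.fn == len(truths) - mr.tp


class TestPrecisionRecallF:
    def test_direct_formula(self):
        p, r, f, deg = precision_recall_f(9, 1, 3)
        assert (p, r) == (0.9, 0.75)
        assert f == pytest.approx(0.818, abs=5e-4)
        assert not deg

    def test_degenerate_zero_counts(self):
        assert precision_recall_f(0, 0, 0) == (0.0, 0.0, 0.0, True)

    def test_reported_training_set_f(self):
        """Harmonic mean of precision 0.84 and recall 0.91 is 0.87 (2 dp)."""
        p, r = 0.84, 0.91
        f = 2 * p * r / (p + r)
        assert round(f, 2) == 0.87

    @given(tp=st.integers(0, 500), fp=st.integers(0, 500),
           fn=st.integers(0, 500))
    @settings(max_examples=150, deadline=None)
    def test_agrees_with_confusion_recomputation(self, tp, fp, fn):
        p, r, f, deg = precision_recall_f(tp, fp, fn)
        if tp + fp:
            assert p == tp / (tp + fp)
        if tp + fn:
            assert r == tp / (tp + fn)
        if p + r:
            assert f == pytest.approx(2 * p * r / (p + r))
        # harmonic-mean bounds
        assert 0.0 <= f <= 2 * min(p, r) + 1e-12
        assert f <= (p + r) / 2 + 1e-12

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            precision_recall_f(-1, 0, 0)


class TestPRCurve:
    def test_oracle_is_perfect_everywhere(self, small_scene):
        pts = pr_curve(WindowOracle(small_scene.annotations), [small_scene],
                       PatchConfig(120, 30), DetectionConfig(),
                       radius_px=30.0)
        assert len(pts) == 19
        for pt in pts:
            assert pt.precision == pt.recall == pt.f_score == 1.0

    def test_recall_non_increasing(self, small_scene):
        pts = pr_curve(WindowOracle(small_scene.annotations), [small_scene],
                       PatchConfig(120, 30), DetectionConfig())
        recalls = [pt.recall for pt in pts]
        assert all(a >= b - 1e-12 for a, b in zip(recalls, recalls[1:]))

    def test_empty_scene_list_rejected(self):
        with pytest.raises(ValueError):
            pr_curve(None, [])

    def test_f_iso_reference_levels(self):
        assert f_iso_levels() == (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


class TestCountAccuracy:
    def test_perfect_counts(self):
        acc = count_accuracy([(10, 10), (40, 40)])
        assert acc.mean_accuracy_pct == 100.0

    def test_36pct_deviation_is_64pct_accuracy(self):
        assert count_accuracy([(64, 100)]).mean_accuracy_pct == pytest.approx(64.0)
        assert count_accuracy([(136, 100)]).mean_accuracy_pct == pytest.approx(64.0)

    def test_symmetric_overcount(self):
        assert count_accuracy([(150, 100)]).mean_accuracy_pct == pytest.approx(50.0)

    def test_floor_at_zero(self):
        assert count_accuracy([(500, 100)]).mean_accuracy_pct == 0.0

    def test_zero_manual_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="zero manual"):
            acc = count_accuracy([(5, 0), (10, 10)])
        assert len(acc.per_image) == 1


class TestCountsRegression:
    def test_exact_line(self):
        pairs = [(2 * m + 1, m) for m in range(1, 6)]
        reg = fit_counts_regression(pairs)
        assert reg.slope == pytest.approx(2.0)
        assert reg.intercept == pytest.approx(1.0)
        assert reg.r_squared == pytest.approx(1.0)

    def test_constant_computed_gives_zero_r2(self):
        reg = fit_counts_regression([(5, 1), (5, 2), (5, 3), (5, 4)])
        assert reg.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_normal_equations(self):
        """{(1,1),(2,2),(3,2),(4,4)} as (computed, manual): slope 0.9,
        intercept 0, R^2 = 1 - 0.70/4.75."""
        reg = fit_counts_regression([(1, 1), (2, 2), (2, 3), (4, 4)])
        assert reg.slope == pytest.approx(0.9)
        assert reg.intercept == pytest.approx(0.0, abs=1e-12)
        assert reg.r_squared == pytest.approx(1 - 0.70 / 4.75)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_counts_regression([(1, 1), (2, 2)])

    def test_zero_variance_manual(self):
        with pytest.raises(ValueError, match="variance"):
            fit_counts_regression([(1, 3), (2, 3), (4, 3)])
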