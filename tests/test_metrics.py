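"""Threshold grid, PR sweep, and trapezoidal AP against enumeration oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcsem.metrics import (average_precision, exponential_thresholds,
                           mean_average_precision, pr_points)


def oracle_ap(scores, labels):
    """Independent brute-force AP: enumerate every distinct prediction set.

    Sweeps one threshold per unique score (plus the all-negative cut above
    the maximum), computes (recall, precision) by direct counting, sorts by
    recall, applies the same padding conventions, and integrates with the
    trapezoid rule written out longhand.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = labels.sum()
    cuts = sorted(set(scores)) + [np.inf]
    points = []
    for t in cuts:
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        pp = int(pred.sum())
        prec = tp / pp if pp else 1.0
        points.append((tp / n_pos, prec))
    points.sort(key=lambda rp: (rp[0], -rp[1]))
    if points[0][0] > 0:
        points.insert(0, (0.0, 1.0))
    if points[-1][0] < 1:
        points.append((1.0, n_pos / len(labels)))
    ap = 0.0
    for (r0, p0), (r1, p1) in zip(points, points[1:]):
        ap += 0.5 * (p0 + p1) * (r1 - r0)
    return ap


class TestExponentialThresholds:
    def test_endpoints_are_exact(self):
        t = exponential_thresholds(2, 3.0)
        assert t.tolist() == [0.0, 1.0]

    def test_linear_limit_is_uniform(self):
        t = exponential_thresholds(3, 1e-9)
        assert np.allclose(t, [0.0, 0.5, 1.0], atol=1e-9)

    def test_closed_form_n5_k5(self):
        t = exponential_thresholds(5, 5.0)
        expected = (np.expm1(5.0 * np.linspace(0, 1, 5))) / np.expm1(5.0)
        assert np.allclose(t, expected, atol=1e-12)
        assert np.all(np.diff(t) > 0)

    def test_rejects_degenerate_requests(self):
        with pytest.raises(ValueError):
            exponential_thresholds(1)
        with pytest.raises(ValueError):
            exponential_thresholds(10, curvature=0.0)


class TestPRPoints:
    def test_perfect_scores_trace_the_top_edge(self):
        labels = np.array([1, 0, 1, 0, 1])
        curve = pr_points(labels.astype(float), labels)
        # every operating point above threshold 0 is perfect; threshold 0
        # contributes the recall-1 anchor at precision = prevalence
        assert np.all(curve.precision[:-1] == 1.0)
        assert curve.precision[-1] == pytest.approx(0.6)
        assert curve.recall[0] == 0.0 and curve.recall[-1] == 1.0
        assert average_precision(curve) == pytest.approx(1.0, abs=1e-12)

    def test_constant_scores_give_single_operating_point(self):
        scores = np.full(6, 0.4)
        labels = np.array([1, 0, 0, 1, 0, 0])
        curve = pr_points(scores, labels, thresholds=np.array([0.0, 0.4, 1.0]))
        # every threshold <= 0.4 predicts everything, 1.0 predicts nothing
        interior = set(zip(curve.recall, curve.precision))
        assert (1.0, 2 / 6) in interior and (0.0, 1.0) in interior

    def test_four_score_example_matches_enumeration(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6])
        labels = np.array([1, 0, 1, 0])
        thresholds = np.array([0.0, 0.6, 0.7, 0.8, 0.9, 1.0])
        curve = pr_points(scores, labels, thresholds)
        ap = average_precision(curve)
        assert ap == pytest.approx(oracle_ap(scores, labels), abs=1e-9)
        # the five distinct prediction sets appear as operating points
        assert (0.5, 1.0) in set(zip(curve.recall, curve.precision))
        assert (1.0, 2 / 3) in set(zip(curve.recall, curve.precision))

    def test_all_negative_class_is_an_error(self):
        with pytest.raises(ValueError, match="no positive"):
            pr_points(np.array([0.1, 0.2]), np.array([0, 0]))

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            pr_points(np.array([0.1, 0.2]), np.array([0, 2]))


class TestAveragePrecision:
    def test_perfect_separation_scores_one(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert average_precision(pr_points(scores, labels)) == pytest.approx(1.0, abs=1e-12)

    def test_single_trapezoid_closed_form(self):
        from pcsem.metrics import PRCurve
        p = 0.3
        assert average_precision(PRCurve([0.0, 1.0], [1.0, p])) == pytest.approx((1 + p) / 2)

    @pytest.mark.parametrize("n,seed", [(30, 0), (57, 1), (101, 2)])
    def test_exhaustive_thresholds_match_oracle(self, n, seed):
        r = np.random.default_rng(seed)
        scores = r.random(n)
        labels = (r.random(n) < 0.4).astype(int)
        labels[0] = 1
        cuts = np.unique(np.concatenate([[0.0, 1.0], scores]))
        ap = average_precision(pr_points(scores, labels, cuts))
        assert ap == pytest.approx(oracle_ap(scores, labels), abs=1e-9)

    def test_grid_ap_converges_to_exhaustive(self):
        r = np.random.default_rng(7)
        scores = np.clip(r.normal(0.3, 0.25, 1000), 0, 1)
        labels = (r.random(1000) < scores).astype(int)
        exact = oracle_ap(scores, labels)
        gaps = []
        for n_points in (10, 100, 1000):
            ap = average_precision(pr_points(scores, labels,
                                             exponential_thresholds(n_points)))
            gaps.append(abs(ap - exact))
        assert gaps[2] <= gaps[0]
        assert gaps[2] < 0.005

    def test_invariant_under_monotone_score_transforms(self):
        r = np.random.default_rng(3)
        scores = r.random(80)
        labels = (r.random(80) < 0.3).astype(int)
        labels[:2] = 1

        def ap_exhaustive(s):
            cuts = np.unique(np.concatenate([[s.min()], s]))
            return average_precision(pr_points(s, labels, cuts))

        base = ap_exhaustive(scores)
        for f in (lambda s: s ** 3, lambda s: 1 / (1 + np.exp(-4 * (s - 0.5)))):
            assert ap_exhaustive(f(scores)) == pytest.approx(base, abs=1e-9)

    def test_small_sample_label_enumeration_matches_oracle(self):
        """All label patterns on 10 fixed scores agree with brute force."""
        r = np.random.default_rng(11)
        scores = r.random(10)
        cuts = np.unique(np.concatenate([[0.0, 1.0], scores]))
        for bits in range(1, 2 ** 10):
            labels = np.array([(bits >> i) & 1 for i in range(10)])
            ap = average_precision(pr_points(scores, labels, cuts))
            assert abs(ap - oracle_ap(scores, labels)) < 1e-9

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 1, width=32), st.booleans()),
                    min_size=2, max_size=40).filter(lambda v: any(b for _, b in v)))
    def test_ap_bounds_and_perfect_ranking(self, pairs):
        scores = np.array([s for s, _ in pairs], dtype=float)
        labels = np.array([int(b) for _, b in pairs])
        cuts = np.unique(np.concatenate([[0.0, 1.0], scores]))
        ap = average_precision(pr_points(scores, labels, cuts))
        assert -1e-12 <= ap <= 1 + 1e-12
        pos, neg = scores[labels == 1], scores[labels == 0]
        if len(neg) and pos.min() > neg.max():
            assert ap == pytest.approx(1.0, abs=1e-12)


class TestMeanAveragePrecision:
    def test_oracle_scores_give_map_one(self):
        labels = (np.random.default_rng(0).random((50, 7)) < 0.3).astype(int)
        labels[0] = 1
        res = mean_average_precision(labels.astype(float), labels)
        assert res.map == pytest.approx(1.0, abs=1e-12)

    def test_single_class_map_equals_its_ap(self):
        r = np.random.default_rng(5)
        scores = r.random((40, 1))
        labels = (r.random((40, 1)) < 0.5).astype(int)
        labels[0, 0] = 1
        res = mean_average_precision(scores, labels)
        assert res.map == pytest.approx(res.per_class_ap[0])

    def test_random_scores_ap_approaches_prevalence(self):
        """With uninformative scores AP concentrates at class prevalence."""
        r = np.random.default_rng(42)
        aps = []
        for _ in range(20):
            scores = r.random((10_000, 1))
            labels = (r.random((10_000, 1)) < 0.5).astype(int)
            aps.append(mean_average_precision(scores, labels).map)
        assert np.mean(aps) == pytest.approx(0.5, abs=0.02)

    def test_positive_free_classes_are_excluded_and_reported(self):
        scores = np.random.default_rng(1).random((30, 3))
        labels = np.zeros((30, 3), dtype=int)
        labels[:10, 0] = 1
        res = mean_average_precision(scores, labels)
        assert res.excluded_classes == [1, 2]
        assert res.evaluated_classes == [0]
        with pytest.raises(ValueError):
            mean_average_precision(scores, np.zeros_like(labels))
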