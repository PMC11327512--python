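"""Metrics: decision rule, confusion-matrix identities, AUC against a
brute-force pair-counting oracle, and fold summaries."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from swallownet.evaluation import (
    ConfusionCounts,
    MetricsReport,
    classify,
    compute_report,
    confusion_counts,
    confusion_metrics,
    roc_auc,
    roc_points,
    summarize_folds,
)


def brute_force_auc(labels, scores):
    """Independent oracle: count concordant pairs, ties at half weight."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestClassify:
    def test_normal_when_normal_prob_exceeds_half(self):
        assert classify(0.49) == 0  # P(normal)=0.51 -> normal

    def test_tie_goes_to_aspiration(self):
        # strict "exceeding": P(normal)=0.50 is NOT normal
        assert classify(0.5) == 1

    def test_zero_threshold_boundary(self):
        assert classify(0.99, threshold=0.0) == 0
        assert classify(1.0, threshold=0.0) == 1  # P(normal)=0 never exceeds 0

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            classify(1.2)


class TestConfusionMetrics:
    def test_hand_arithmetic_oracle(self):
        m = confusion_metrics(ConfusionCounts(tp=9, fn=1, tn=8, fp=2))
        assert m["sensitivity"] == pytest.approx(90.0)
        assert m["specificity"] == pytest.approx(80.0)
        assert m["ppv"] == pytest.approx(81.8182, abs=1e-3)
        assert m["npv"] == pytest.approx(88.8889, abs=1e-3)
        assert m["accuracy"] == pytest.approx(85.0)
        assert m["f1"] == pytest.approx(0.8571, abs=1e-4)

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(tp=5, fn=0, tn=7, fp=0))
        for key in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            assert m[key] == 100.0
        assert m["f1"] == 1.0

    def test_sensitivity_complements_on_swap(self):
        a = confusion_metrics(ConfusionCounts(tp=3, fn=7, tn=5, fp=5))
        b = confusion_metrics(ConfusionCounts(tp=7, fn=3, tn=5, fp=5))
        assert a["sensitivity"] + b["sensitivity"] == pytest.approx(100.0)

    def test_zero_denominator_is_nan_not_zero(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))
        assert math.isnan(m["sensitivity"])
        assert math.isnan(m["npv"]) is False  # tn+fn = 5 is fine

    @given(
        st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30)
    )
    def test_accuracy_identity(self, tp, fp, tn, fn):
        # accuracy == (sens*P + spec*N)/(P+N) whenever all terms are defined
        if tp + fn == 0 or tn + fp == 0:
            return
        m = confusion_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        p, n = tp + fn, tn + fp
        expected = (m["sensitivity"] * p + m["specificity"] * n) / (p + n)
        assert m["accuracy"] == pytest.approx(expected)


class TestRocAuc:
    def test_worked_example(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(4, 50))
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.uniform(size=n), 2)  # rounding induces ties
            assert roc_auc(labels, scores) == pytest.approx(
                brute_force_auc(labels, scores)
            )

    def test_negation_symmetry(self):
        rng = np.random.default_rng(1)
        labels = [0, 1] * 10
        scores = rng.uniform(size=20)  # continuous: tie-free
        assert roc_auc(labels, scores) + roc_auc(labels, -scores) == pytest.approx(1.0)


class TestRocPoints:
    def test_curve_spans_origin_to_corner_monotonically(self):
        pts = roc_points([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8])
        assert (pts[0]["fpr"], pts[0]["tpr"]) == (0.0, 0.0)
        assert (pts[-1]["fpr"], pts[-1]["tpr"]) == (1.0, 1.0)
        assert all(b["fpr"] >= a["fpr"] for a, b in zip(pts, pts[1:]))
        assert all(b["tpr"] >= a["tpr"] for a, b in zip(pts, pts[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_points([0, 0], [0.1, 0.2])


class TestSummarizeFolds:
    def _reports(self, aucs):
        return [
            MetricsReport(
                auc=a, accuracy=80.0, sensitivity=80.0, specificity=80.0,
                f1=0.8, ppv=80.0, npv=80.0,
            )
            for a in aucs
        ]

    def test_t_interval_arithmetic(self):
        # {0.7, 0.8, 0.9}: mean 0.8, half-width 4.303 * 0.1 / sqrt(3)
        s = summarize_folds(self._reports([0.7, 0.8, 0.9]))["auc"]
        assert s.mean == pytest.approx(0.8)
        assert s.ci_low == pytest.approx(0.5515, abs=1e-3)
        assert s.ci_high == pytest.approx(1.0485, abs=1e-3)
        assert s.max == pytest.approx(0.9)

    def test_identical_reports_collapse_ci(self):
        s = summarize_folds(self._reports([0.75] * 10))["auc"]
        assert s.ci_low == pytest.approx(s.mean) == pytest.approx(s.ci_high)

    def test_symmetric_values_symmetric_ci(self):
        s = summarize_folds(self._reports([0.0] * 5 + [1.0] * 5))["auc"]
        assert s.mean == pytest.approx(0.5)
        assert s.mean - s.ci_low == pytest.approx(s.ci_high - s.mean)

    def test_mean_is_arithmetic_mean(self):
        aucs = [0.61, 0.72, 0.83, 0.94]
        s = summarize_folds(self._reports(aucs))["auc"]
        assert s.mean == pytest.approx(np.mean(aucs))

    def test_single_report_rejected(self):
        with pytest.raises(ValueError):
            summarize_folds(self._reports([0.8]))

    def test_intervals_not_clipped(self):
        # near-ceiling folds push the upper bound past 100, by design
        reports = [
            MetricsReport(
                auc=0.9, accuracy=99.0, sensitivity=99.0, specificity=99.0,
                f1=0.9, ppv=99.0, npv=99.0,
            ),
            MetricsReport(
                auc=0.9, accuracy=80.0, sensitivity=80.0, specificity=80.0,
                f1=0.9, ppv=80.0, npv=80.0,
            ),
        ]
        s = summarize_folds(reports)["sensitivity"]
        assert s.ci_high > 100.0


class TestComputeReport:
    def test_end_to_end_report(self):
        labels = [0, 0, 0, 1, 1]
        probs = [0.1, 0.2, 0.7, 0.8, 0.3]
        r = compute_report(labels, probs)
        # predictions: 0,0,1,1,0 -> tp=1 fp=1 tn=2 fn=1
        assert r.accuracy == pytest.approx(60.0)
        assert r.sensitivity == pytest.approx(50.0)
        assert r.auc == pytest.approx(brute_force_auc(labels, probs))
        assert r.loss > 0
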