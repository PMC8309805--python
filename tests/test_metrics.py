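"""Evaluation metrics against brute-force oracles and algebraic identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mammocad import (
    ConfusionCounts,
    UndefinedMetricError,
    accuracy,
    auc,
    confusion_from_predictions,
    f1_score,
    fpi,
    full_report,
    precision,
    sensitivity,
    specificity,
)


def mann_whitney_auc(y_true, scores):
    """O(n^2) pair-counting oracle with half credit for ties."""
    pos = [s for s, y in zip(scores, y_true) if y == 1]
    neg = [s for s, y in zip(scores, y_true) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_predictions(self):
        c = confusion_from_predictions([1, 1, 0, 0], [1, 1, 0, 0])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)

    def test_fully_wrong_predictions(self):
        c = confusion_from_predictions([1, 0], [0, 1])
        assert (c.tp, c.fn, c.fp, c.tn) == (0, 1, 1, 0)

    def test_matches_nested_loop_oracle(self, rng):
        yt = rng.integers(0, 2, size=200)
        yp = rng.integers(0, 2, size=200)
        c = confusion_from_predictions(yt, yp)
        tallies = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
        for t, p in zip(yt, yp):
            key = ("t" if t == p else "f") + ("p" if p == 1 else "n")
            tallies[key] += 1
        assert (c.tp, c.tn, c.fp, c.fn) == (
            tallies["tp"], tallies["tn"], tallies["fp"], tallies["fn"]
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_from_predictions([0, 1], [0])


class TestRateFormulas:
    def test_sensitivity_values(self):
        assert sensitivity(ConfusionCounts(9, 0, 0, 1, 10)) == pytest.approx(0.9)
        assert sensitivity(ConfusionCounts(5, 2, 1, 0, 8)) == 1.0
        assert sensitivity(ConfusionCounts(760, 0, 0, 0, 760)) == 1.0

    def test_fpi_values(self):
        assert fpi(ConfusionCounts(1, 1, 0, 0, 6)) == 0.0
        assert fpi(ConfusionCounts(0, 0, 12, 1, 6)) == pytest.approx(2.0)
        assert fpi(ConfusionCounts(0, 0, 49, 1, 20)) == pytest.approx(2.45)

    def test_accuracy_values(self):
        assert accuracy(ConfusionCounts(5, 5, 0, 0, 10)) == 1.0
        assert accuracy(ConfusionCounts(25, 25, 25, 25, 100)) == 0.5
        assert accuracy(ConfusionCounts(30, 50, 10, 10, 100)) == pytest.approx(0.8)

    def test_zero_denominators_raise(self):
        no_pos = ConfusionCounts(0, 5, 0, 0, 5)
        with pytest.raises(UndefinedMetricError):
            sensitivity(no_pos)
        with pytest.raises(UndefinedMetricError):
            precision(no_pos)
        with pytest.raises(UndefinedMetricError):
            specificity(ConfusionCounts(5, 0, 0, 0, 5))

    def test_sensitivity_complements_miss_rate(self, rng):
        for _ in range(50):
            tp, fn = rng.integers(1, 100, size=2)
            c = ConfusionCounts(int(tp), 0, 0, int(fn), int(tp + fn))
            assert sensitivity(c) + fn / (tp + fn) == pytest.approx(1.0)

    def test_accuracy_is_prevalence_weighted_mix(self, rng):
        for _ in range(50):
            tp, tn, fp, fn = (int(v) for v in rng.integers(1, 50, size=4))
            c = ConfusionCounts(tp, tn, fp, fn, tp + tn + fp + fn)
            prev = (tp + fn) / c.total
            mix = prev * sensitivity(c) + (1 - prev) * specificity(c)
            assert accuracy(c) == pytest.approx(mix)


class TestAuc:
    def test_perfect_separation(self):
        y = [0, 0, 1, 1]
        s = [0.1, 0.2, 0.8, 0.9]
        assert auc(y, s) == 1.0
        report = full_report(y, s)
        assert report.auc == 1.0 and report.f1 == 1.0

    def test_uninformative_ties_give_half(self):
        assert auc([0, 1, 0, 1], [0.5] * 4) == pytest.approx(0.5)

    def test_matches_pair_counting_oracle(self, rng):
        y = rng.integers(0, 2, size=20)
        y[0], y[1] = 0, 1  # both classes present
        s = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=20)  # force ties
        assert abs(auc(y, s) - mann_whitney_auc(y, s)) < 1e-12

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        s = rng.random(50)
        assert auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auc([1, 1, 1], [0.2, 0.5, 0.9])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.tuples(st.integers(0, 1), st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0])),
            min_size=4,
            max_size=30,
        ).filter(lambda v: len({y for y, _ in v}) == 2)
    )
    def test_sweep_equals_pair_count_property(self, pairs):
        y = [p[0] for p in pairs]
        s = [p[1] for p in pairs]
        assert abs(auc(y, s) - mann_whitney_auc(y, s)) < 1e-12


class TestFullReport:
    def test_consistent_with_argmax_confusion(self, rng):
        y = rng.integers(0, 2, size=100)
        y[:2] = [0, 1]
        s = rng.random(100)
        report = full_report(y, s, threshold=0.5)
        c = confusion_from_predictions(y, (s >= 0.5).astype(int))
        assert report.sensitivity == pytest.approx(sensitivity(c))
        assert report.specificity == pytest.approx(specificity(c))
        assert report.accuracy == pytest.approx(accuracy(c))
        assert report.f1 == pytest.approx(f1_score(c))
        assert report.fpi == pytest.approx(fpi(c))
        assert report.recall == report.sensitivity

    def test_single_class_reports_nan_auc(self):
        report = full_report([1, 1, 1], [0.9, 0.8, 0.7])
        assert np.isnan(report.auc)
        assert report.sensitivity == 1.0

    def test_rate_metrics_within_unit_interval(self, rng):
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        s = rng.random(60)
        report = full_report(y, s)
        for key, value in report.as_dict().items():
            if key != "fpi":
                assert 0.0 <= value <= 1.0
        assert report.fpi >= 0.0

    def test_invalid_scores_rejected(self):
        with pytest.raises(ValueError):
            full_report([0, 1], [0.5, 1.2])
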