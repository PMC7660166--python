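"""ROC/AUC, Youden cutoff, confusion metrics and score normalization."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mietox import evaluation as ev


def pair_enumeration_auc(scores, labels):
    """Independent oracle: count active/inactive pairs (ties half)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def exhaustive_youden(scores, labels):
    """Independent oracle: scan every distinct threshold for max J."""
    best_c, best_j = None, -np.inf
    for c in sorted(set(scores)):
        calls = [1 if s >= c else 0 for s in scores]
        tp = sum(1 for y, p in zip(labels, calls) if y == 1 and p == 1)
        fn = sum(1 for y, p in zip(labels, calls) if y == 1 and p == 0)
        tn = sum(1 for y, p in zip(labels, calls) if y == 0 and p == 0)
        fp = sum(1 for y, p in zip(labels, calls) if y == 0 and p == 1)
        j = tp / (tp + fn) + tn / (tn + fp) - 1
        if j > best_j:  # strict: keeps the smallest tied threshold
            best_c, best_j = c, j
    return best_c, best_j


binary_instances = st.lists(
    st.tuples(st.floats(0, 1, allow_nan=False, width=16), st.integers(0, 1)),
    min_size=4,
    max_size=12,
).filter(lambda xs: len({y for _, y in xs}) == 2)


class TestRocAuc:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ((0.9, 0.8, 0.2, 0.1), (1, 1, 0, 0), 1.0),  # perfect separation
            ((0.9, 0.8, 0.2, 0.1), (0, 0, 1, 1), 0.0),  # anti-separation
            ((0.9, 0.6, 0.4, 0.1), (1, 0, 1, 0), 0.75),  # one inverted pair of four
        ],
    )
    def test_known_auc(self, scores, labels, expected):
        _, auc = ev.compute_roc_auc(scores, labels)
        assert auc == pytest.approx(expected)

    def test_single_class_undefined(self):
        with pytest.raises(ev.UndefinedAUCError):
            ev.compute_roc_auc([0.1, 0.9], [1, 1])

    @given(binary_instances)
    @settings(max_examples=80, deadline=None)
    def test_auc_matches_pair_enumeration(self, instance):
        scores = [s for s, _ in instance]
        labels = [y for _, y in instance]
        _, auc = ev.compute_roc_auc(scores, labels)
        assert auc == pytest.approx(pair_enumeration_auc(scores, labels))


class TestYouden:
    def test_perfect_separation_gap(self):
        curve, _ = ev.compute_roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        # any cutoff in (0.2, 0.8] gives J=1; smallest distinct score wins
        assert ev.youden_threshold(curve) == pytest.approx(0.8)

    def test_derived_example(self):
        scores, labels = [0.9, 0.6, 0.4, 0.1], [1, 0, 1, 0]
        curve, _ = ev.compute_roc_auc(scores, labels)
        oracle_c, _ = exhaustive_youden(scores, labels)
        assert ev.youden_threshold(curve) == pytest.approx(oracle_c)

    def test_all_scores_equal_is_degenerate(self):
        curve, _ = ev.compute_roc_auc([0.5, 0.5, 0.5], [1, 0, 1])
        with pytest.warns(UserWarning, match="degenerate"):
            c = ev.youden_threshold(curve)
        assert c == pytest.approx(0.5)
        assert max(curve.se + curve.sp - 1.0) == pytest.approx(0.0)

    @given(binary_instances)
    @settings(max_examples=80, deadline=None)
    def test_matches_exhaustive_scan(self, instance):
        scores = [s for s, _ in instance]
        labels = [y for _, y in instance]
        curve, _ = ev.compute_roc_auc(scores, labels)
        oracle_c, oracle_j = exhaustive_youden(scores, labels)
        c = ev.youden_threshold(curve)
        assert c == pytest.approx(oracle_c)
        assert max(curve.se + curve.sp - 1.0) == pytest.approx(oracle_j)


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = ev.compute_metrics(ev.ConfusionCounts(tp=2, tn=2, fp=0, fn=0))
        assert (m.se, m.sp, m.acc, m.bac, m.mcc) == (1, 1, 1, 1, 1)

    def test_chance_classifier(self):
        m = ev.compute_metrics(ev.ConfusionCounts(tp=1, tn=1, fp=1, fn=1))
        assert m.mcc == pytest.approx(0.0)
        assert m.bac == pytest.approx(0.5)

    def test_specificity_uses_false_positives(self):
        # SP = TN/(TN+FP): with FN=0 a TN/(TN+FN) misreading would give 1.0
        m = ev.compute_metrics(ev.ConfusionCounts(tp=5, tn=8, fp=2, fn=0))
        assert m.sp == pytest.approx(0.8)

    def test_zero_denominator_flags_metric(self):
        m = ev.compute_metrics(ev.ConfusionCounts(tp=0, tn=5, fp=1, fn=0))
        assert math.isnan(m.se) and "se" in m.undefined
        assert math.isnan(m.bac) and "bac" in m.undefined
        assert m.sp == pytest.approx(5 / 6)  # others still returned

    @given(
        st.tuples(*[st.integers(0, 200)] * 4).filter(lambda c: sum(c) > 0)
    )
    @settings(max_examples=100, deadline=None)
    def test_bac_identity_and_ranges(self, counts):
        tp, tn, fp, fn = counts
        m = ev.compute_metrics(ev.ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        if not math.isnan(m.bac):
            assert m.bac == pytest.approx((m.se + m.sp) / 2, abs=0)
        for v in (m.se, m.sp, m.acc, m.bac):
            assert math.isnan(v) or 0 <= v <= 1
        assert math.isnan(m.mcc) or -1 <= m.mcc <= 1


class TestNormalizeScore:
    def test_square_root_case(self):
        # c = 0.25 -> exponent 1/2
        assert ev.normalize_score(0.0625, 0.25) == pytest.approx(0.25)

    def test_identity_at_half(self):
        x = np.linspace(0, 1, 11)
        assert ev.normalize_score(x, 0.5) == pytest.approx(x)

    @pytest.mark.parametrize("c", [0.01, 0.1, 0.25, 0.5, 0.73, 0.99])
    def test_anchors_and_monotonicity(self, c):
        assert ev.normalize_score(0.0, c) == pytest.approx(0.0)
        assert ev.normalize_score(c, c) == pytest.approx(0.5)
        assert ev.normalize_score(1.0, c) == pytest.approx(1.0)
        x = np.linspace(0, 1, 101)
        assert np.all(np.diff(ev.normalize_score(x, c)) > 0)

    @pytest.mark.parametrize("c", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_cutoff_rejected(self, c):
        with pytest.raises(ValueError):
            ev.normalize_score(0.5, c)


class TestSummaries:
    def test_mean_of_two_targets(self):
        frame = pd.DataFrame({"bac": [0.7, 0.9]})
        out = ev.summarize_means(frame)
        assert out.loc["bac", "mean"] == pytest.approx(0.8)

    def test_undefined_entries_skipped(self):
        frame = pd.DataFrame({"auc": [0.8, np.nan, 0.6], "bac": [0.5, 0.7, 0.9]})
        out = ev.summarize_means(frame)
        assert out.loc["auc", "n"] == 2
        assert out.loc["auc", "mean"] == pytest.approx(0.7)

    def test_display_round_half_up(self):
        assert ev.display_round(0.8275) == 0.828
        assert ev.display_round(0.7655) == 0.766
        assert ev.display_round(0.8665) == 0.867
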