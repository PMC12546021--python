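"""Metric arithmetic, curve areas, and agreement statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from coloqc.evaluation import (
    ConfusionCounts,
    agreement,
    class_metrics,
    evaluate_predictions,
    f1_score,
    pr_ap,
    roc_auc,
    weighted_average,
)

# ---------------------------------------------------------------------------
# scalar metrics


class TestClassMetrics:
    def test_published_style_f1_arithmetic(self):
        # F1 from a high-precision/low-sensitivity pair, to printed precision
        assert 100 * f1_score(0.9997, 0.8621) == pytest.approx(92.59, abs=0.01)
        # and from a balanced pair, to one decimal
        assert round(100 * f1_score(0.9407, 0.9823), 1) == 96.1

    def test_forced_arithmetic_cases(self):
        m = class_metrics(ConfusionCounts(tp=5, tn=0, fp=0, fn=5))
        assert m.sensitivity == 0.5
        assert m.precision == 1.0
        assert m.f1 == pytest.approx(2 * 1.0 * 0.5 / 1.5)

    def test_zero_denominators_are_flagged_not_fatal(self):
        m = class_metrics(ConfusionCounts(tp=0, tn=10, fp=0, fn=0))
        assert m.precision == 0.0 and m.sensitivity == 0.0
        assert "precision_undefined" in m.flags

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            class_metrics(ConfusionCounts(0, 0, 0, 0))

    @given(st.floats(0.01, 1.0), st.floats(0.01, 1.0))
    @settings(max_examples=1000, deadline=None)
    def test_f1_below_arithmetic_mean(self, p, s):
        f1 = f1_score(p, s)
        assert f1 <= (p + s) / 2 + 1e-12
        if abs(p - s) < 1e-12:
            assert f1 == pytest.approx((p + s) / 2)


class TestWeightedAverage:
    def test_constant_vector(self):
        assert weighted_average([0.9, 0.9, 0.9], [1, 1, 1]) == pytest.approx(0.9)

    def test_degenerate_weighting(self):
        assert weighted_average([0.1, 0.5, 0.9], [1, 0, 0]) == 0.1

    def test_matches_loop_oracle_and_bounds(self, rng):
        for _ in range(20):
            values = rng.uniform(0, 1, 5)
            weights = rng.uniform(0, 2, 5)
            expected = sum(v * w for v, w in zip(values, weights)) / weights.sum()
            got = weighted_average(values, weights)
            assert got == pytest.approx(expected)
            assert values.min() - 1e-12 <= got <= values.max() + 1e-12

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            weighted_average([1.0], [0.5, 0.5])


# ---------------------------------------------------------------------------
# curves


def mann_whitney_auc(scores, truth):
    """Pairwise-comparison oracle: P(score+ > score-) + 0.5 P(tie)."""
    pos = [s for s, t in zip(scores, truth) if t]
    neg = [s for s, t in zip(scores, truth) if not t]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]).area == pytest.approx(1.0)

    def test_uninformative_scores_give_chance(self):
        assert roc_auc([0.5] * 10, [1, 0] * 5).area == pytest.approx(0.5)

    def test_equals_mann_whitney_oracle(self, rng):
        for _ in range(20):
            scores = np.round(rng.uniform(0, 1, 30), 2)  # rounding forces ties
            truth = rng.integers(0, 2, 30)
            if truth.sum() in (0, 30):
                continue
            assert roc_auc(scores, truth).area == pytest.approx(
                mann_whitney_auc(scores, truth), abs=1e-12
            )

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=40)
        truth = rng.integers(0, 2, 40)
        a1 = roc_auc(scores, truth).area
        a2 = roc_auc(np.exp(3 * scores), truth).area
        assert a1 == pytest.approx(a2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestPrAp:
    def test_perfect_ranking(self):
        assert pr_ap([0.9, 0.8, 0.2], [1, 1, 0]).area == pytest.approx(1.0)

    def test_all_positive_truth(self, rng):
        scores = rng.uniform(0, 1, 10)
        assert pr_ap(scores, [1] * 10).area == pytest.approx(1.0)

    def test_agrees_with_threshold_sweep_oracle(self, rng):
        for _ in range(10):
            scores = rng.uniform(0, 1, 30)
            truth = rng.integers(0, 2, 30)
            if truth.sum() == 0:
                continue
            # exhaustive sweep over the distinct scores, trapezoid in recall
            pts = []
            for thr in sorted(set(scores), reverse=True):
                sel = scores >= thr
                tp = int((truth[sel] == 1).sum())
                pts.append((tp / truth.sum(), tp / sel.sum()))
            recalls = [0.0] + [r for r, _ in pts]
            precisions = [pts[0][1]] + [p for _, p in pts]
            expected = sum(
                (r1 - r0) * (p0 + p1) / 2
                for r0, r1, p0, p1 in zip(recalls, recalls[1:], precisions, precisions[1:])
            )
            assert pr_ap(scores, truth).area == pytest.approx(expected, abs=1e-12)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_ap([0.3, 0.4], [0, 0])


# ---------------------------------------------------------------------------
# agreement


class TestAgreement:
    def test_identical_series(self, rng):
        a = rng.normal(300, 50, 30)
        rep = agreement(a, a)
        assert rep.icc == pytest.approx(1.0)
        assert rep.bias == 0.0
        assert rep.loa_high - rep.loa_low == pytest.approx(0.0)
        assert "pearson_zero_variance" not in rep.flags
        assert "wilcoxon_all_zero" in rep.flags and rep.wilcoxon_p == 1.0

    def test_constant_offset_geometry(self, rng):
        a = rng.normal(300, 50, 30)
        rep = agreement(a, a + 10.0)
        assert rep.bias == pytest.approx(-10.0)
        assert rep.loa_low == pytest.approx(-10.0)
        assert rep.loa_high == pytest.approx(-10.0)
        assert rep.icc < 1.0
        assert rep.pearson_r == pytest.approx(1.0)

    def test_simulated_raters_recover_closed_form_icc(self):
        # truth sd 15 s, independent rater noise sd 5 s:
        # ICC(A,1) expectation = 15^2 / (15^2 + 5^2) = 0.9
        rng = np.random.default_rng(0)
        truth = rng.normal(300, 15, 200)
        a = truth + rng.normal(0, 5, 200)
        b = truth + rng.normal(0, 5, 200)
        rep = agreement(a, b)
        assert rep.icc == pytest.approx(0.9, abs=0.05)
        assert rep.icc_ci95[0] < rep.icc < rep.icc_ci95[1]

    def test_matches_pingouin_icc_a1(self, rng):
        pingouin = pytest.importorskip("pingouin")
        a = rng.normal(300, 60, 48)
        b = a + rng.normal(-11, 30, 48)
        rep = agreement(a, b)
        df = pd.DataFrame(
            {
                "rating": np.r_[a, b],
                "target": np.r_[np.arange(48), np.arange(48)],
                "rater": ["A"] * 48 + ["B"] * 48,
            }
        )
        tab = pingouin.intraclass_corr(
            df, targets="target", raters="rater", ratings="rating"
        ).set_index("Type")
        assert rep.icc == pytest.approx(tab.loc["ICC(A,1)", "ICC"], abs=1e-9)

    def test_wilcoxon_conventions(self, rng):
        a = rng.normal(300, 60, 20)
        b = a + rng.normal(5, 10, 20)
        rep = agreement(a, b)
        ref = stats.wilcoxon(a - b, mode="exact")  # n <= 25 -> exact null
        assert rep.wilcoxon_w == ref.statistic
        assert rep.wilcoxon_p == pytest.approx(ref.pvalue)

    def test_short_or_mismatched_series_rejected(self):
        with pytest.raises(ValueError):
            agreement([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            agreement([1.0, 2.0, 3.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# multiclass report


def test_perfect_predictions_report(scenario0):
    labels = [scenario0.sidecar[i].label for i in range(len(scenario0.sidecar))]
    report = evaluate_predictions(labels, labels, confidences=[1.0] * len(labels))
    assert report["weighted"]["accuracy"] == 100.0
    for cls in report["classes"].values():
        assert cls["f1"] == 100.0
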