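"""ROC/Youden/confusion statistics against brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from ctcdx.diagnostics import (
    ConfusionMatrix,
    chi2_2x2,
    compare_auc,
    confusion_at,
    diagnostic_metrics,
    fit_logistic,
    group_tests,
    roc_curve,
    youden_cutoff,
)
from ctcdx.errors import InputValidationError


def auc_pairwise(scores, labels):
    """Tie-corrected pairwise probability oracle, O(n_pos * n_neg)."""
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else 0.5 if p == q else 0.0
    return total / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_curve([5, 6, 1, 2], [True, True, False, False])
        assert roc.auc == 1.0

    def test_all_ties(self):
        roc = roc_curve([3, 3, 3, 3], [True, True, False, False])
        assert roc.auc == 0.5

    def test_trapezoid_auc_equals_pairwise_oracle(self):
        rng = np.random.default_rng(42)
        scores = rng.integers(0, 8, size=30).astype(float)
        labels = rng.random(30) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        roc = roc_curve(scores, labels)
        assert roc.auc == pytest.approx(auc_pairwise(scores, labels),
                                        abs=1e-12)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.4
        roc = roc_curve(scores, labels)
        assert roc.sensitivity[0] == 0.0 and roc.fpr[0] == 0.0
        assert roc.sensitivity[-1] == 1.0 and roc.fpr[-1] == 1.0
        assert (np.diff(roc.sensitivity) >= 0).all()
        assert (np.diff(roc.fpr) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(InputValidationError, match="single class"):
            roc_curve([1, 2, 3], [True, True, True])

    def test_ci_contains_point_estimate(self):
        roc = roc_curve([1, 2, 3, 4, 2, 5], [False, False, True, True,
                                             False, True])
        lo, hi = roc.ci95
        assert lo <= roc.auc <= hi


class TestYouden:
    def test_worked_example_midpoint(self):
        res = youden_cutoff([3, 3, 4, 1, 2],
                            [True, True, True, False, False])
        assert res.cutoff == 2.5
        assert res.j == pytest.approx(1.0)

    def test_matches_threshold_enumeration(self):
        rng = np.random.default_rng(7)
        scores = rng.integers(0, 10, size=60).astype(float)
        labels = np.concatenate([np.ones(30, bool), np.zeros(30, bool)])
        scores[:30] += 1  # some signal
        res = youden_cutoff(scores, labels)
        # brute force over a fine grid of cutoffs
        best_j = max(
            ((scores > c) & labels).sum() / 30
            + (~(scores > c) & ~labels).sum() / 30 - 1.0
            for c in np.arange(scores.min() - 1, scores.max() + 1, 0.25)
        )
        assert res.j == pytest.approx(best_j, abs=1e-12)

    def test_tie_broken_toward_lower_cutoff(self):
        # J = 0.5 both at 1.5 and 2.5: lower (more sensitive) wins
        scores = [1, 2, 2, 3]
        labels = [False, True, False, True]
        res = youden_cutoff(scores, labels)
        assert res.cutoff == 1.5

    def test_perfect_separation_gives_unit_sens_and_spec(self):
        res = youden_cutoff([5, 6, 1, 2], [True, True, False, False])
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_cutoff_invariant_to_far_away_patients(self):
        scores = [1.0, 1.0, 4.0, 4.0, 4.0]
        labels = [False, False, True, True, True]
        base = youden_cutoff(scores, labels).cutoff
        extended = youden_cutoff(
            scores + [100.0] * 5 + [-50.0] * 5,
            labels + [True] * 5 + [False] * 5,
        ).cutoff
        assert base == extended == 2.5


class TestConfusionAndMetrics:
    def test_reconstructed_screening_table(self):
        scores = np.array([4] * 51 + [1] * 46 + [4] * 5 + [1] * 20, float)
        labels = np.array([True] * 97 + [False] * 25)
        cm = confusion_at(scores, labels, 2.5)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (51, 5, 46, 20)
        m = diagnostic_metrics(cm)
        assert round(m["ppv"] * 100, 1) == 91.1
        assert round(m["npv"] * 100, 1) == 30.3
        assert round(m["malignancy_rate_neg"] * 100, 1) == 69.7
        assert m["sensitivity"] == pytest.approx(51 / 97)
        assert m["specificity"] == pytest.approx(0.800)

    def test_degenerate_cutoffs(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([False, True, False, True])
        low = confusion_at(scores, labels, 0.0)
        assert low.fn == 0 and low.tn == 0
        high = confusion_at(scores, labels, 10.0)
        assert high.tp == 0 and high.fp == 0

    def test_perfect_classifier_metrics(self):
        m = diagnostic_metrics(ConfusionMatrix(10, 0, 0, 10))
        assert m["sensitivity"] == m["specificity"] == m["ppv"] == m["npv"] == 1.0
        assert m["malignancy_rate_neg"] == 0.0

    def test_zero_denominator_reported_as_undefined(self):
        m = diagnostic_metrics(ConfusionMatrix(tp=0, fp=0, fn=3, tn=4))
        assert math.isnan(m["ppv"])
        assert not math.isnan(m["npv"])

    def test_bayes_consistency_of_predictive_values(self):
        cm = ConfusionMatrix(51, 5, 46, 20)
        m = diagnostic_metrics(cm)
        prev = cm.n_malignant / (cm.n_malignant + cm.n_benign)
        sens, spec = m["sensitivity"], m["specificity"]
        ppv_bayes = sens * prev / (sens * prev + (1 - spec) * (1 - prev))
        npv_bayes = spec * (1 - prev) / (
            spec * (1 - prev) + (1 - sens) * prev
        )
        assert m["ppv"] == pytest.approx(ppv_bayes, abs=1e-12)
        assert m["npv"] == pytest.approx(npv_bayes, abs=1e-12)


class TestCompareAuc:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=40)
        y = rng.random(40) < 0.5
        res = compare_auc(s, s, y, paired=True)
        assert res["p"] == 1.0

    def test_paired_delong_matches_permutation_oracle(self):
        rng = np.random.default_rng(3)
        n = 50
        y = np.concatenate([np.ones(25, bool), np.zeros(25, bool)])
        a = rng.normal(size=n) + y * 0.8
        b = rng.normal(size=n) + y * 0.5
        res = compare_auc(a, b, y, paired=True)

        def auc(s):
            from scipy.stats import rankdata
            r = rankdata(s)
            m = y.sum()
            return (r[y].sum() - m * (m + 1) / 2) / (m * (n - m))

        obs = abs(auc(a) - auc(b))
        n_perm, hits = 4000, 0
        for _ in range(n_perm):
            swap = rng.random(n) < 0.5
            aa = np.where(swap, b, a)
            bb = np.where(swap, a, b)
            if abs(auc(aa) - auc(bb)) >= obs - 1e-12:
                hits += 1
        p_perm = hits / n_perm
        mc_se = math.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(res["p"] - p_perm) < 4 * mc_se + 0.02

    def test_unpaired_comparison_returns_valid_p(self):
        rng = np.random.default_rng(9)
        a, ya = rng.normal(size=30), rng.random(30) < 0.5
        b, yb = rng.normal(size=40), rng.random(40) < 0.5
        res = compare_auc(a, b, ya, yb, paired=False)
        assert 0.0 < res["p"] <= 1.0

    def test_paired_with_mismatched_lengths_rejected(self):
        with pytest.raises(InputValidationError, match="same patients"):
            compare_auc([1, 2, 3, 4], [1, 2, 3], [True, False, True, False],
                        paired=True)


class TestLogistic:
    def test_single_binary_covariate_matches_odds_ratio(self):
        # 2x2 (a, b, c, d) = (30, 20, 15, 35): OR = ad/bc
        x = [1] * 50 + [0] * 50
        y = [1] * 30 + [0] * 20 + [1] * 15 + [0] * 35
        df = pd.DataFrame({"exposed": x})
        fit = fit_logistic(df, y)
        assert fit.loc["exposed", "or_"] == pytest.approx(
            (30 * 35) / (20 * 15), rel=1e-5
        )

    def test_null_covariate_gives_or_near_one(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"noise": rng.integers(0, 2, 400).astype(bool)})
        y = rng.integers(0, 2, 400)
        fit = fit_logistic(df, y)
        assert fit.loc["noise", "ci_lo"] < 1.0 < fit.loc["noise", "ci_hi"]

    def test_categorical_dummy_coding_with_reference(self):
        rng = np.random.default_rng(4)
        lr = rng.choice(["2", "3", "4X"], size=300)
        y = rng.integers(0, 2, 300)
        fit = fit_logistic(pd.DataFrame({"lung_rads": lr}), y,
                           reference={"lung_rads": "2"})
        assert set(fit.index) == {"lung_rads[3]", "lung_rads[4X]"}

    def test_separation_flagged_with_unbounded_ci(self):
        df = pd.DataFrame({"x": [0, 0, 0, 1, 1, 1]})
        fit = fit_logistic(df, [0, 0, 0, 1, 1, 1])
        assert fit.attrs["separation"]
        assert fit.loc["x", "ci_hi"] == np.inf


class TestGroupTests:
    def test_identical_groups_mann_whitney_p_one(self):
        res = group_tests([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                          ["a"] * 3 + ["b"] * 3)
        assert res["test"] == "mann_whitney_u"
        assert res["p"] == pytest.approx(1.0)

    def test_nodule_nature_table_highly_significant(self):
        # benign solid/subsolid 14/10 vs malignant 18/78
        res = chi2_2x2(14, 18, 10, 78)
        assert res["p"] < 0.001

    def test_chi2_statistic_matches_textbook_formula(self):
        a, b, c, d = 8, 4, 3, 9
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        res = chi2_2x2(a, b, c, d)
        assert res["statistic"] == pytest.approx(expected, abs=1e-12)

    def test_categorical_values_dispatch_to_chi2(self):
        vals = ["solid"] * 20 + ["subsolid"] * 10 + ["solid"] * 5 + [
            "subsolid"] * 25
        grp = ["benign"] * 30 + ["malignant"] * 30
        res = group_tests(vals, grp)
        assert res["test"] == "chi2"
        assert res["p"] < 0.01
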