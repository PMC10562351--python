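"""Metric identities, brute-force agreement, inference behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fedaki.errors import UndefinedMetricError
from fedaki.evaluation import (auroc, calibration_curve, cohort_summary,
                               compare_auroc, evaluate, net_benefit,
                               perm_importance, threshold_metrics)

from oracles import brute_auroc, brute_mannwhitney_u


class TestAuroc:
    def test_perfect_ranking(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auroc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_worked_example(self):
        assert auroc([0.7, 0.4, 0.6, 0.3], [1, 0, 1, 0]) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            auroc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            n = int(rng.integers(5, 200))
            scores = np.round(rng.random(n), 2)  # induce ties
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]
            assert auroc(scores, labels) == pytest.approx(
                brute_auroc(scores, labels), abs=1e-12)


class TestThresholdMetrics:
    def test_perfect_scores(self):
        assert threshold_metrics([0.9, 0.1], [1, 0], 0.5) == (1, 1, 1, 1)

    def test_threshold_zero_calls_everyone_positive(self):
        sens, spec, prec, acc = threshold_metrics(
            [0.3, 0.6, 0.2], [1, 0, 0], 0.0)
        assert sens == 1.0 and spec == 0.0
        assert acc == pytest.approx(1 / 3)  # prevalence

    def test_hand_computed_confusion(self):
        # TP=3, FP=1, FN=1, TN=5
        scores = [0.9, 0.8, 0.7, 0.6, 0.4] + [0.3, 0.2, 0.2, 0.1, 0.1]
        labels = [1, 1, 1, 0, 1] + [0, 0, 0, 0, 0]
        sens, spec, prec, acc = threshold_metrics(scores, labels, 0.5)
        assert (sens, spec, prec, acc) == \
            (0.75, pytest.approx(5 / 6), 0.75, 0.8)

    def test_no_positive_calls_yield_zero_precision(self):
        assert threshold_metrics([0.1, 0.2], [1, 0], 0.9)[2] == 0.0


class TestCalibration:
    def test_probabilities_matching_rates_sit_on_diagonal(self):
        probs = np.repeat([0.15, 0.45, 0.85], 40)
        labels = np.concatenate([
            np.r_[np.ones(6), np.zeros(34)],
            np.r_[np.ones(18), np.zeros(22)],
            np.r_[np.ones(34), np.zeros(6)]])
        for mean_p, obs, _ in calibration_curve(probs, labels):
            assert obs == pytest.approx(mean_p, abs=1e-9)

    def test_single_extreme_bin(self):
        bins = calibration_curve(np.ones(50), np.zeros(50))
        assert bins == [(1.0, 0.0, 50)]

    def test_bin_counts_sum_to_n(self):
        rng = np.random.default_rng(0)
        p = rng.random(500)
        y = rng.integers(0, 2, 500)
        assert sum(c for _, _, c in calibration_curve(p, y)) == 500


class TestNetBenefit:
    def test_perfect_classifier_net_benefit_is_prevalence(self):
        labels = np.r_[np.ones(30), np.zeros(70)].astype(int)
        probs = labels.astype(float)
        df = net_benefit(probs, labels, np.arange(0.05, 0.95, 0.05))
        assert np.allclose(df["net_benefit"], 0.3)
        assert np.all(df["treat_none"] == 0.0)

    def test_treat_all_approaches_prevalence_at_low_threshold(self):
        labels = np.r_[np.ones(30), np.zeros(70)].astype(int)
        df = net_benefit(labels.astype(float), labels, [0.001])
        assert df["treat_all"].iloc[0] == pytest.approx(0.3, abs=1e-2)

    def test_hand_computed_point(self):
        # TP=3, FP=1, n=10, p_t=0.2 -> 0.3 - 0.1 * 0.25 = 0.275
        probs = [0.9, 0.9, 0.9, 0.9, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]
        labels = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
        df = net_benefit(probs, labels, [0.2])
        assert df["net_benefit"].iloc[0] == pytest.approx(0.275)

    def test_never_exceeds_prevalence(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = 200
            probs = rng.random(n)
            labels = rng.integers(0, 2, n)
            df = net_benefit(probs, labels, np.arange(0.05, 0.95, 0.05))
            assert np.all(df["net_benefit"] <= labels.mean() + 1e-12)


class TestPermImportance:
    class _Linear:
        def __init__(self, w):
            self.w = np.asarray(w)

        def predict_proba(self, X):
            p = 1 / (1 + np.exp(-(X @ self.w)))
            return np.column_stack([1 - p, p])

    def test_strongest_true_coefficient_ranks_first(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((2000, 4))
        X[:, 3] = 1.0  # constant column
        w = np.array([2.0, 0.5, 0.0, 0.0])
        y = (rng.random(2000) < 1 / (1 + np.exp(-(X @ w)))).astype(int)
        rep = perm_importance(self._Linear(w), X, y,
                              ["big", "small", "noise", "const"], seed=0)
        assert rep["feature"].iloc[0] == "big"
        assert abs(rep.set_index("feature").loc["noise", "mean_drop"]) < 0.01
        assert rep.set_index("feature").loc["const", "mean_drop"] == 0.0


class TestCompareAuroc:
    def test_identical_scores_give_zero_delta(self):
        rng = np.random.default_rng(0)
        s = rng.random(100)
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        res = compare_auroc(s, s, y, n_boot=200, seed=0)
        assert res["delta"] == 0.0 and res["p_value"] > 0.9

    def test_swapping_negates_delta(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(80), rng.random(80)
        y = rng.integers(0, 2, 80)
        y[:2] = [0, 1]
        r1 = compare_auroc(a, b, y, n_boot=50, seed=0)
        r2 = compare_auroc(b, a, y, n_boot=50, seed=0)
        assert r1["delta"] == pytest.approx(-r2["delta"])

    def test_clear_improvement_excludes_zero(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 500)
        y[:2] = [0, 1]
        random_scores = rng.random(500)
        perfect = y + 0.01 * rng.random(500)
        res = compare_auroc(random_scores, perfect, y, n_boot=500, seed=0)
        assert res["ci_low"] > 0 and res["p_value"] < 0.01


class TestCohortSummary:
    def test_identical_groups_not_significant(self):
        df = pd.DataFrame({"x": np.arange(20.0)})
        out = cohort_summary(df, df.copy())
        assert not out["significant"].iloc[0]

    def test_shifted_variable_flagged(self):
        rng = np.random.default_rng(0)
        a = pd.DataFrame({"x": rng.normal(0, 1, 200)})
        b = pd.DataFrame({"x": rng.normal(2, 1, 200)})
        out = cohort_summary(a, b)
        assert out["p_value"].iloc[0] < 0.001 and out["significant"].iloc[0]

    def test_chi_square_without_continuity_correction(self):
        # 2x2 table [[30,70],[70,30]] -> Pearson chi2 = 32
        a = pd.DataFrame({"flag": [True] * 30 + [False] * 70})
        b = pd.DataFrame({"flag": [True] * 70 + [False] * 30})
        out = cohort_summary(a, b, categorical=["flag"])
        expect_p = stats.chi2.sf(32.0, 1)
        assert out["p_value"].iloc[0] == pytest.approx(expect_p, rel=1e-9)

    def test_mannwhitney_matches_exhaustive_ranking(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 25)
        b = rng.normal(0.5, 1, 20)
        u = brute_mannwhitney_u(a, b)
        stat, _ = stats.mannwhitneyu(a, b, alternative="two-sided")
        assert stat == pytest.approx(u)
        out = cohort_summary(pd.DataFrame({"x": a}), pd.DataFrame({"x": b}))
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        assert out["p_value"].iloc[0] == pytest.approx(p)


def test_evaluate_bundle_is_consistent():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 300)
    y[:2] = [0, 1]
    p = np.clip(0.3 * y + 0.4 * rng.random(300), 0, 1)
    rep = evaluate(p, y, threshold=0.5)
    assert 0 <= rep.auroc <= 1
    assert rep.n == 300 and rep.n_pos == y.sum()
    assert sum(c for _, _, c in rep.calibration) == 300
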