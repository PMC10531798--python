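"""Statistics layer against brute-force and hand-computed oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from lafq.errors import SeparationError, StatisticsError
from lafq.outcome_stats import (analyze_cohort, group_compare, km_logrank,
                                logistic_fit, roc_auc)
from lafq.phantom import generate_cohort


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def auc_pair_counting(score, label):
    """AUC as explicit pair enumeration: wins + half ties over all pairs."""
    pos = [s for s, y in zip(score, label) if y == 1]
    neg = [s for s, y in zip(score, label) if y == 0]
    wins = sum(1.0 for p in pos for n in neg if p > n)
    ties = sum(0.5 for p in pos for n in neg if p == n)
    return (wins + ties) / (len(pos) * len(neg))


def fisher_enumeration(table):
    """Two-sided Fisher p by full enumeration over fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

class TestRocAuc:
    def test_perfect_separation_and_all_ties(self):
        assert roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]).auc == 1.0
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]).auc == 0.5

    def test_worked_example(self):
        curve = roc_auc([0.9, 0.4, 0.3, 0.5], [1, 0, 1, 0])
        assert curve.auc == pytest.approx(0.5)  # 2 wins / 4 pairs

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_pair_counting_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        label = np.zeros(n, dtype=int)
        label[: int(rng.integers(1, n))] = 1
        rng.shuffle(label)
        if label.sum() in (0, n):
            label[0] = 1 - label[0]
        score = rng.integers(0, 6, size=n).astype(float)  # many ties
        assert roc_auc(score, label).auc == pytest.approx(
            auc_pair_counting(score, label), abs=1e-12)

    def test_curve_monotone_and_trapezoid_consistent(self):
        rng = np.random.default_rng(7)
        score = rng.normal(size=60)
        label = (rng.random(60) < 0.4).astype(int)
        curve = roc_auc(score, label)
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)
        assert np.trapezoid(curve.tpr, curve.fpr) == pytest.approx(
            curve.auc, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(StatisticsError):
            roc_auc([1.0, 2.0], [1, 1])

    @given(st.lists(st.tuples(st.integers(0, 6), st.booleans()),
                    min_size=4, max_size=25))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_label_flip_symmetry(self, pairs):
        score = np.array([s for s, _ in pairs], dtype=float)
        label = np.array([int(y) for _, y in pairs])
        assume(0 < label.sum() < len(label))
        a = roc_auc(score, label).auc
        b = roc_auc(score, 1 - label).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

class TestLogisticFit:
    def test_known_model_coefficient_recovery(self):
        rng = np.random.default_rng(21)
        n = 2000
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-1.0 + 0.8 * x)))
        y = (rng.random(n) < p).astype(int)
        (eff,) = logistic_fit(y, pd.DataFrame({"x": x}), mode="univariate")
        assert abs(eff.coef - 0.8) < 0.1
        assert eff.ci_low < eff.odds_ratio < eff.ci_high

    def test_null_covariate_ci_coverage(self):
        rng = np.random.default_rng(22)
        covered = 0
        for _ in range(100):
            x = rng.normal(size=500)
            y = (rng.random(500) < 0.4).astype(int)
            (eff,) = logistic_fit(y, pd.DataFrame({"x": x}))
            covered += eff.ci_low <= 1.0 <= eff.ci_high
        assert covered >= 93

    def test_constant_covariate_rejected(self):
        y = np.array([0, 1] * 10)
        with pytest.raises(StatisticsError, match="constant"):
            logistic_fit(y, pd.DataFrame({"x": np.ones(20)}))

    def test_perfect_separation_flagged_without_estimates(self):
        x = np.concatenate([np.zeros(15), np.ones(15)])
        y = x.astype(int)
        with pytest.raises(SeparationError):
            logistic_fit(y, pd.DataFrame({"x": x}))

    def test_multivariate_returns_all_covariates(self):
        rng = np.random.default_rng(23)
        X = pd.DataFrame({"a": rng.normal(size=300),
                          "b": rng.normal(size=300)})
        y = (rng.random(300) < 0.5).astype(int)
        effects = logistic_fit(y, X, mode="multivariate")
        assert [e.name for e in effects] == ["a", "b"]


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

class TestKmLogrank:
    def test_no_censoring_empirical_survival(self):
        fit = km_logrank([1, 2, 3, 4], [1, 1, 1, 1])
        assert fit.survival_at(0, 0.5) == 1.0
        assert fit.survival_at(0, 2.5) == pytest.approx(0.5)
        assert fit.survival_at(0, 4.0) == pytest.approx(0.0)

    def test_hand_computed_product_limit_with_censoring(self):
        # events at 1, 2, 4, 5; censored at 3:
        # S(1)=4/5, S(2)=4/5·3/4=3/5, S(4)=3/5·1/2, S(5)=0
        fit = km_logrank([1, 2, 3, 4, 5], [1, 1, 0, 1, 1])
        assert fit.survival_at(0, 1) == pytest.approx(0.8)
        assert fit.survival_at(0, 2) == pytest.approx(0.6)
        assert fit.survival_at(0, 4) == pytest.approx(0.3)
        assert fit.survival_at(0, 5) == pytest.approx(0.0)
        assert np.all(np.diff(fit.survival[0]) <= 1e-12)

    def test_identical_groups_null_logrank(self):
        times = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        events = [1, 1, 0, 1, 1] * 2
        group = [0] * 5 + [1] * 5
        fit = km_logrank(times, events, group)
        assert fit.logrank_statistic == pytest.approx(0.0, abs=1e-12)
        assert fit.logrank_p == pytest.approx(1.0)

    def test_group_relabeling_invariance(self):
        rng = np.random.default_rng(31)
        times = rng.exponential(10, size=40)
        events = (rng.random(40) < 0.7).astype(int)
        group = (rng.random(40) < 0.5).astype(int)
        a = km_logrank(times, events, group)
        b = km_logrank(times, events, 1 - group)
        assert a.logrank_statistic == pytest.approx(b.logrank_statistic)
        assert 0 < a.logrank_p <= 1

    def test_empty_group_and_no_events_rejected(self):
        with pytest.raises(StatisticsError):
            km_logrank([1, 2, 3], [0, 0, 0])


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

class TestGroupCompare:
    def test_identical_samples_t(self):
        x = [1.0, 2.0, 3.0, 4.0]
        t, p = group_compare(x, x, kind="t")
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_fisher_balanced_table(self):
        _, p = group_compare(np.array([[5, 5], [5, 5]]), kind="fisher")
        assert p == pytest.approx(1.0)

    def test_fisher_beta_blocker_table(self):
        # recurrence: 2/12 on beta-blockers; no recurrence: 20/24
        _, p = group_compare(np.array([[2, 10], [20, 4]]), kind="fisher")
        assert p < 0.001

    @pytest.mark.parametrize("table", [
        [[2, 10], [20, 4]], [[5, 5], [5, 5]], [[1, 9], [9, 1]],
        [[0, 12], [7, 8]], [[3, 14], [11, 2]], [[8, 0], [2, 13]],
    ])
    def test_fisher_matches_full_enumeration(self, table):
        _, p = group_compare(np.array(table), kind="fisher")
        assert p == pytest.approx(fisher_enumeration(table), abs=1e-10)

    def test_malformed_table_rejected(self):
        with pytest.raises(StatisticsError):
            group_compare(np.array([[1, 2, 3], [4, 5, 6]]), kind="fisher")
        with pytest.raises(StatisticsError):
            group_compare(np.array([[1.5, 2.0], [3.0, 4.0]]), kind="fisher")


# ---------------------------------------------------------------------------
# Cohort-level
# ---------------------------------------------------------------------------

class TestAnalyzeCohort:
    def test_null_cohort_auc_centered_on_half(self):
        aucs = []
        for seed in range(200):
            cohort = generate_cohort(40, effect=0.0, seed=seed)
            df = cohort.clinical
            aucs.append(roc_auc(df["delta_pv_mean"].to_numpy(),
                                df["recurrence"].to_numpy()).auc)
        assert abs(float(np.mean(aucs)) - 0.5) < 0.05

    def test_effect_cohort_beats_null(self):
        null = generate_cohort(200, effect=0.0, seed=5).clinical
        strong = generate_cohort(200, effect=5.0, seed=5).clinical
        auc_null = roc_auc(null["delta_pv_mean"], null["recurrence"]).auc
        auc_strong = roc_auc(strong["delta_pv_mean"], strong["recurrence"]).auc
        assert auc_strong > 0.8
        assert auc_strong > auc_null

    def test_full_report_structure(self):
        cohort = generate_cohort(60, effect=1.0, seed=2)
        report = analyze_cohort(cohort.clinical)
        assert set(report.roc) == {"delta_la", "delta_pv_mean",
                                   "n_pv_no_increase"}
        assert len(report.group_comparisons) == 3
        assert {"odds_ratio", "ci_low", "ci_high"} <= set(
            report.univariate.columns)
        text = report.to_text()
        assert "AUC" in text and "odds_ratio" in text.lower() or "OR" in text

    def test_single_class_outcome_rejected(self):
        cohort = generate_cohort(20, effect=0.0, seed=3).clinical
        cohort["recurrence"] = 1
        with pytest.raises(StatisticsError):
            analyze_cohort(cohort)
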