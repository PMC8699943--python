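"""Diagnostic-accuracy core: confusion metrics, AUC, ROC, Youden cutoffs.

Independent oracles used here: a brute-force pair-counting AUC, an
exhaustive grid scan for the Youden optimum, a per-subject tally for
confusion counts, and scikit-learn's ROC AUC as a cross-check.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flindex as fx
from flindex.accuracy import INTEGER_GRID, DegenerateLabelsError

from conftest import random_scores_labels


# ---------------------------------------------------------------------------
# oracles


def brute_force_auc(scores, labels):
    """Double loop over all positive x negative pairs, ties counted 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_tally(scores, labels, cutoff):
    tp = fp = tn = fn = 0
    for s, l in zip(scores, labels):
        if s >= cutoff:
            tp, fp = tp + l, fp + (not l)
        else:
            fn, tn = fn + l, tn + (not l)
    return tp, fp, tn, fn


def exhaustive_youden_scan(scores, labels, grid_values):
    best_cut, best_j = None, -np.inf
    for c in grid_values:
        tp, fp, tn, fn = brute_force_tally(scores, labels, c)
        j = tp / (tp + fn) + tn / (tn + fp) - 1.0
        if j > best_j:  # strict: keeps the smallest cutoff on ties
            best_cut, best_j = c, j
    return best_cut, best_j


# ---------------------------------------------------------------------------


class TestConfusionAndMetrics:
    def test_perfectly_separated_toy(self):
        c = fx.confusion_at_cutoff([10, 20, 30, 40],
                                   [False, False, True, True], 30)
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 0, 2, 0)

    def test_cutoff_zero_makes_everyone_positive(self):
        c = fx.confusion_at_cutoff([10, 20, 30, 40],
                                   [False, False, True, True], 0)
        assert c.fn == 0 and c.fp == 2

    def test_matches_brute_force_tally(self, rng):
        scores, labels = random_scores_labels(rng, n=20)
        for cutoff in np.linspace(-2, 3, 7):
            c = fx.confusion_at_cutoff(scores, labels, cutoff)
            assert (c.tp, c.fp, c.tn, c.fn) == brute_force_tally(
                scores, labels, cutoff)

    def test_chance_performance(self):
        m = fx.metrics_from_counts(fx.ConfusionCounts(tp=25, fp=25, tn=25, fn=25))
        assert m.se == m.sp == m.ppv == m.npv == 0.5
        assert m.plr == m.nlr == 1.0 and m.youden_j == 0.0

    def test_perfect_classifier(self):
        m = fx.metrics_from_counts(fx.ConfusionCounts(tp=50, fp=0, tn=50, fn=0))
        assert m.se == m.sp == 1.0 and m.youden_j == 1.0
        assert m.nlr == 0.0 and m.plr_infinite

    def test_hand_computed_ratios(self):
        m = fx.metrics_from_counts(fx.ConfusionCounts(tp=30, fp=20, tn=40, fn=10))
        assert m.se == pytest.approx(0.75)
        assert m.sp == pytest.approx(40 / 60)
        assert m.ppv == pytest.approx(0.6)
        assert m.npv == pytest.approx(0.8)
        assert m.plr == pytest.approx(0.75 / (1 - 40 / 60))
        assert m.nlr == pytest.approx(0.25 / (40 / 60))

    def test_degenerate_counts_raise(self):
        with pytest.raises(DegenerateLabelsError):
            fx.metrics_from_counts(fx.ConfusionCounts(tp=3, fp=0, tn=0, fn=2))

    def test_single_class_labels_raise(self):
        with pytest.raises(DegenerateLabelsError):
            fx.confusion_at_cutoff([1, 2, 3], [True, True, True], 2)


class TestMetricsFromRates:
    def test_published_rule_out_row(self):
        m = fx.metrics_from_rates(0.714, 0.774, prevalence=0.614)
        assert m.plr == pytest.approx(3.16, abs=0.005)
        assert m.ppv == pytest.approx(0.834, abs=5e-4)
        assert m.npv == pytest.approx(0.630, abs=5e-4)

    def test_youden_identity(self):
        assert fx.metrics_from_rates(0.734, 0.761).youden_j == pytest.approx(0.495)

    def test_perfect_rates(self):
        m = fx.metrics_from_rates(1.0, 1.0, prevalence=0.3)
        assert m.ppv == m.npv == 1.0 and m.youden_j == 1.0

    def test_sp_one_flags_infinite_plr(self):
        assert fx.metrics_from_rates(0.5, 1.0).plr_infinite

    def test_sp_zero_marks_nlr_undefined(self):
        assert math.isnan(fx.metrics_from_rates(0.5, 0.0).nlr)

    def test_reproduces_empirical_ppv_npv_at_sample_prevalence(self, rng):
        scores, labels = random_scores_labels(rng, n=80)
        counts = fx.confusion_at_cutoff(scores, labels, 0.4)
        emp = fx.metrics_from_counts(counts)
        adj = fx.metrics_from_rates(emp.se, emp.sp,
                                    prevalence=counts.n_positive / counts.n)
        assert adj.ppv == pytest.approx(emp.ppv)
        assert adj.npv == pytest.approx(emp.npv)


class TestAuc:
    def test_perfect_separation(self):
        assert fx.auc_mann_whitney([1, 2, 3, 4],
                                   [False, False, True, True]) == 1.0

    def test_interleaved_pairs(self):
        # pairs (2,1) (2,3) (4,1) (4,3): 3 wins of 4
        assert fx.auc_mann_whitney([1, 2, 3, 4],
                                   [False, True, False, True]) == 0.75

    def test_all_ties_give_half(self):
        assert fx.auc_mann_whitney([5.0] * 6,
                                   [True, False] * 3) == pytest.approx(0.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_equals_brute_force_pair_counting(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 200))
        scores, labels = random_scores_labels(r, n=n)
        if r.random() < 0.5:
            scores = np.round(scores)  # force ties
        assert fx.auc_mann_whitney(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12)

    def test_cross_check_against_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores, labels = random_scores_labels(rng, n=150)
        assert fx.auc_mann_whitney(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_label_inversion_maps_auc_to_complement(self, rng):
        scores, labels = random_scores_labels(rng, n=90)
        a = fx.auc_mann_whitney(scores, labels)
        b = fx.auc_mann_whitney(scores, ~labels)
        assert a + b == pytest.approx(1.0, abs=1e-12)


class TestAucCi:
    def test_delong_interval_contains_point_and_is_deterministic(self, rng):
        scores, labels = random_scores_labels(rng, n=200)
        auc = fx.auc_mann_whitney(scores, labels)
        lo, hi = fx.auc_ci(scores, labels, method="delong")
        assert lo <= auc <= hi
        assert fx.auc_ci(scores, labels, method="delong") == (lo, hi)

    def test_bootstrap_deterministic_given_seed(self, rng):
        scores, labels = random_scores_labels(rng, n=60)
        a = fx.auc_ci(scores, labels, method="bootstrap", n_boot=200, seed=5)
        b = fx.auc_ci(scores, labels, method="bootstrap", n_boot=200, seed=5)
        assert a == b

    def test_delong_and_bootstrap_agree_on_moderate_sample(self, rng):
        scores, labels = random_scores_labels(rng, n=200)
        auc = fx.auc_mann_whitney(scores, labels)
        d_lo, d_hi = fx.auc_ci(scores, labels, method="delong")
        b_lo, b_hi = fx.auc_ci(scores, labels, method="bootstrap",
                               n_boot=500, seed=1)
        assert d_lo <= auc <= d_hi and b_lo <= auc <= b_hi
        assert max(d_lo, b_lo) < min(d_hi, b_hi)  # intervals overlap

    def test_width_shrinks_with_sample_size(self):
        r = np.random.default_rng(3)
        widths = []
        for n in (50, 2000):
            scores, labels = random_scores_labels(r, n=n, separation=2.0)
            lo, hi = fx.auc_ci(scores, labels, method="delong")
            widths.append(hi - lo)
        assert widths[1] < widths[0]
        assert widths[1] <= 1.0

    def test_too_few_bootstrap_replicates_rejected(self, rng):
        scores, labels = random_scores_labels(rng, n=30)
        with pytest.raises(ValueError):
            fx.auc_ci(scores, labels, method="bootstrap", n_boot=50)


class TestRocCurve:
    def test_hand_constructed_staircase(self):
        roc = fx.roc_curve([1, 2, 3, 4], [False, True, False, True])
        # cutoffs: -inf, 1, 2, 3, 4, +inf
        assert roc.se.tolist() == [1.0, 1.0, 1.0, 0.5, 0.5, 0.0]
        assert roc.sp.tolist() == [0.0, 0.0, 0.5, 0.5, 1.0, 1.0]
        assert roc.auc == 0.75

    def test_monotone_se_sp(self, rng):
        scores, labels = random_scores_labels(rng, n=75)
        roc = fx.roc_curve(scores, labels)
        assert np.all(np.diff(roc.se) <= 0)
        assert np.all(np.diff(roc.sp) >= 0)
        assert roc.auc_ci[0] <= roc.auc <= roc.auc_ci[1]

    def test_duplicated_subject_keeps_monotonicity(self, rng):
        scores, labels = random_scores_labels(rng, n=40)
        scores2 = np.append(scores, scores[0])
        labels2 = np.append(labels, labels[0])
        roc = fx.roc_curve(scores2, labels2)
        assert np.all(np.diff(roc.se) <= 0)

    def test_trapezoid_area_equals_mann_whitney(self, rng):
        scores, labels = random_scores_labels(rng, n=120)
        scores = np.round(scores, 1)  # with ties
        roc = fx.roc_curve(scores, labels)
        fpr = (1.0 - roc.sp)[::-1]
        tpr = roc.se[::-1]
        assert np.trapezoid(tpr, fpr) == pytest.approx(roc.auc, abs=1e-12)


class TestOptimalCutoff:
    def test_perfectly_separated_integer_grid_tie_break(self):
        # any integer cutoff in (10, 20] attains J=1; smallest (11) returned
        scores = [5, 8, 10, 25, 30, 40]
        labels = [False, False, False, True, True, True]
        res = fx.optimal_cutoff_youden(scores, labels, grid="integer")
        assert res.optimal_cutoff == 11.0
        assert res.metrics.youden_j == 1.0

    @pytest.mark.parametrize("grid", ["integer", "observed"])
    def test_equals_exhaustive_scan(self, grid, rng):
        scores = rng.uniform(0, 100, 500)
        labels = rng.random(500) < 1 / (1 + np.exp(-(scores - 50) / 15))
        res = fx.optimal_cutoff_youden(scores, labels, grid=grid)
        grid_values = INTEGER_GRID if grid == "integer" else np.unique(scores)
        cut, j = exhaustive_youden_scan(scores, labels, grid_values)
        assert res.optimal_cutoff == cut
        assert res.metrics.youden_j == pytest.approx(j, abs=1e-12)

    def test_j_at_optimum_dominates_grid(self, rng):
        scores, labels = random_scores_labels(rng, n=300, separation=1.5)
        scores = 50 + 15 * scores
        res = fx.optimal_cutoff_youden(scores, labels, grid="integer")
        for c in INTEGER_GRID:
            m = fx.metrics_from_counts(fx.confusion_at_cutoff(scores, labels, c))
            assert res.metrics.youden_j >= m.youden_j - 1e-12

    def test_score_order_invariance_observed_grid(self, rng):
        scores, labels = random_scores_labels(rng, n=100)
        res = fx.optimal_cutoff_youden(scores, labels, grid="observed")
        transformed = np.exp(scores / 2.0)  # strictly increasing map
        res_t = fx.optimal_cutoff_youden(transformed, labels, grid="observed")
        assert res_t.roc.auc == pytest.approx(res.roc.auc, abs=1e-12)
        assert res_t.optimal_cutoff == pytest.approx(
            np.exp(res.optimal_cutoff / 2.0))
        points = set(zip(res.roc.se.tolist(), res.roc.sp.tolist()))
        points_t = set(zip(res_t.roc.se.tolist(), res_t.roc.sp.tolist()))
        assert points == points_t


class TestEvaluateFixedCutoffs:
    def test_no_score_above_cutoff_boundary(self):
        table = fx.evaluate_fixed_cutoffs([10, 20, 30, 40],
                                          [False, True, False, True],
                                          cutoffs=[60])
        row = table.iloc[0]
        assert row["se"] == 0.0 and row["sp"] == 1.0
        assert math.isnan(row["plr"])  # 0/0: undefined, flagged not silent

    def test_compositional_oracle(self, rng):
        scores, labels = random_scores_labels(rng, n=40)
        scores = 50 + 20 * scores
        table = fx.evaluate_fixed_cutoffs(scores, labels, cutoffs=[30, 60])
        for _, row in table.iterrows():
            m = fx.metrics_from_counts(
                fx.confusion_at_cutoff(scores, labels, row["cutoff"]))
            for k in ("se", "sp", "ppv", "npv", "youden_j"):
                assert row[k] == pytest.approx(getattr(m, k))

    def test_bayes_self_consistency(self, rng):
        scores, labels = random_scores_labels(rng, n=40)
        prev = float(np.mean(labels))
        table = fx.evaluate_fixed_cutoffs(scores, labels, cutoffs=[0.0],
                                          prevalence=prev)
        row = table.iloc[0]
        if not math.isnan(row["ppv"]):
            assert row["ppv_adj"] == pytest.approx(row["ppv"])


class TestStratifiedAnalysis:
    def test_total_equals_pooled_optimum(self, default_cohort):
        results = fx.stratified_analysis(default_cohort, reference="us",
                                         strata="by_sex")
        by_name = {r.stratum: r for r in results}
        cohort = fx.add_fli_column(default_cohort)
        ref = fx.build_reference_labels(cohort, reference="us")
        scores = cohort.loc[ref.index, "fli"].to_numpy()
        pooled = fx.optimal_cutoff_youden(scores, ref.labels, grid="integer")
        assert by_name["total"].optimal_cutoff == pooled.optimal_cutoff
        assert by_name["total"].roc.auc == pytest.approx(pooled.roc.auc)
        assert set(by_name) == {"total", "male", "female"}
        ns = [by_name["male"].n, by_name["female"].n]
        assert sum(ns) == by_name["total"].n  # strata partition the cohort

    def test_single_sex_cohort_skips_missing_stratum(self):
        from conftest import make_cohort

        df = make_cohort(us_steatosis=[True, False, True, False])
        df["sex"] = "male"
        df["tg"] = [150.0, 60.0, 140.0, 70.0]
        with pytest.warns(UserWarning, match="female"):
            results = fx.stratified_analysis(df, reference="us",
                                             strata="by_sex")
        assert {r.stratum for r in results} == {"total", "male"}
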