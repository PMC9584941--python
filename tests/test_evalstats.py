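"""Confusion metrics, exact tests, DeLong AUC, log-SUV linear models."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps
import statsmodels.api as sm

from petnode import (
    CohortConfig,
    ConfusionCounts,
    auc_with_ci,
    compare_auc_paired,
    confusion,
    fisher_exact_2x2,
    fit_log_suv_model,
    generate_cohort,
    kruskal_wallis,
    mcnemar_exact_weighted,
    metrics,
    reconstruct_confusion,
)


class TestConfusionAndMetrics:
    def test_perfect_agreement(self):
        c = confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (c.fp, c.fn) == (0, 0)
        m = metrics(c)
        assert (m.sensitivity, m.specificity, m.mcr, m.fdr) == (1, 1, 0, 0)

    def test_enumerated_cells(self):
        c = confusion([1, 1, 0, 0], [1, 0, 1, 0])
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            confusion([], [])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])

    @pytest.mark.parametrize(
        "cells, expect",
        [
            # expert-rater row of the 675-node tally: MCR 0.1748, FN 16
            ((275, 102, 16, 282), (0.945, 0.734, 0.1748)),
            # fixed SUV-2.5 cut-off row: MCR 0.2919, FN 9
            ((282, 188, 9, 196), (0.969, 0.510, 0.2919)),
        ],
    )
    def test_published_tally_rows(self, cells, expect):
        tp, fp, fn, tn = cells
        m = metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn))
        sens, spec, mcr = expect
        assert m.sensitivity == pytest.approx(sens, abs=5e-4)
        assert m.specificity == pytest.approx(spec, abs=5e-4)
        assert m.mcr == pytest.approx(mcr, abs=5e-5)

    def test_undefined_metric_is_nan_not_error(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=5))
        assert math.isnan(m.sensitivity) and math.isnan(m.fdr)

    def test_fdr_increases_with_fp(self):
        fdrs = [metrics(ConfusionCounts(tp=10, fp=fp, fn=2, tn=50)).fdr
                for fp in range(0, 30, 5)]
        assert fdrs == sorted(fdrs)


class TestReconstruction:
    def test_mlp_row_yields_349_called_positives(self):
        c = reconstruct_confusion(mcr=0.1333, fn=16, n=675, n_positive=291)
        assert (c.tp, c.fp) == (275, 74)
        assert c.n_called_positive == 349

    def test_high_sensitivity_row_yields_488_called_positives(self):
        c = reconstruct_confusion(mcr=0.2978, fn=2, n=675, n_positive=291)
        assert (c.tp, c.fp) == (289, 199)
        assert c.n_called_positive == 488

    def test_zero_error_diagonal(self):
        c = reconstruct_confusion(mcr=0.0, fn=0, n=100, n_positive=40)
        assert (c.tp, c.fp, c.fn, c.tn) == (40, 0, 0, 60)

    def test_inconsistent_inputs_raise(self):
        with pytest.raises(ValueError):
            reconstruct_confusion(mcr=0.01, fn=50, n=100, n_positive=60)

    def test_round_trips_with_confusion_metrics(self, rng):
        for _ in range(50):
            labels = rng.integers(0, 2, size=200)
            calls = rng.integers(0, 2, size=200)
            if labels.sum() == 0:
                labels[0] = 1
            c = confusion(labels, calls)
            m = metrics(c)
            back = reconstruct_confusion(m.mcr, c.fn, c.n, c.n_positive)
            assert (back.tp, back.fp, back.fn, back.tn) == (c.tp, c.fp, c.fn, c.tn)


def _mcnemar_exact_oracle(b, c):
    """Two-sided exact binomial by direct pmf enumeration."""
    n = b + c
    if n == 0:
        return 1.0
    k = min(b, c)
    tail = sum(math.comb(n, i) for i in range(k + 1)) / 2**n
    return min(1.0, 2 * tail)


class TestMcNemar:
    def test_hand_computed_example(self):
        # discordants 1 vs 5 -> p = 2 * (7/64)
        labels = np.zeros(20, int)
        calls_a = np.zeros(20, int)
        calls_b = np.zeros(20, int)
        calls_a[:1] = 1   # A wrong, B right on 1 record
        calls_b[1:6] = 1  # B wrong, A right on 5 records
        res = mcnemar_exact_weighted(calls_a, calls_b, labels, weight_mcn=1)
        assert res.p_value == pytest.approx(0.21875)

    def test_symmetric_discordance_gives_one(self):
        labels = np.zeros(10, int)
        a = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        b = np.array([0, 0, 1, 1, 0, 0, 0, 0, 0, 0])
        for w in (1, 9, 20):
            assert mcnemar_exact_weighted(a, b, labels, w).p_value == 1.0

    def test_zero_discordance_flag(self):
        labels = np.array([1, 0, 1])
        res = mcnemar_exact_weighted(labels, labels, labels, 1)
        assert res.zero_discordance and res.p_value == 1.0

    def test_matches_enumeration_oracle_at_weight_one(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 31))
            labels = rng.integers(0, 2, size=n)
            a = rng.integers(0, 2, size=n)
            b = rng.integers(0, 2, size=n)
            res = mcnemar_exact_weighted(a, b, labels, 1)
            assert res.p_value == pytest.approx(
                _mcnemar_exact_oracle(res.b_star, res.c_star), abs=1e-12)

    def test_weighting_can_shift_significance(self):
        # discordances concentrated on positives gain weight
        labels = np.array([1] * 6 + [0] * 30)
        a = labels.copy()              # A always right
        b = np.concatenate([np.zeros(6, int), np.zeros(30, int)])  # B misses positives
        p1 = mcnemar_exact_weighted(a, b, labels, 1).p_value
        p9 = mcnemar_exact_weighted(a, b, labels, 9).p_value
        assert p9 < p1

    def test_type_one_error_controlled_under_null(self):
        """Two equally wrong classifiers: rejection rate <= 6% at alpha 5%."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            labels = rng.integers(0, 2, size=100)
            a = np.where(rng.random(100) < 0.2, 1 - labels, labels)
            b = np.where(rng.random(100) < 0.2, 1 - labels, labels)
            if mcnemar_exact_weighted(a, b, labels, 1).p_value < 0.05:
                rejections += 1
        assert rejections / n_rep <= 0.06


def _fisher_oracle(table):
    """Hypergeometric enumeration with fixed margins."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    rv = sps.hypergeom(n, r1, c1)
    p_obs = rv.pmf(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = rv.pmf(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


class TestFisher:
    def test_diagonal_table(self):
        assert fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_uniform_table(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == 1.0

    def test_zero_margin_gives_one(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(100):
            cells = rng.integers(0, 11, size=4)
            table = [[int(cells[0]), int(cells[1])],
                     [int(cells[2]), int(cells[3])]]
            if sum(cells) == 0 or min(np.array(table).sum(0).min(),
                                      np.array(table).sum(1).min()) == 0:
                continue
            assert fisher_exact_2x2(table) == pytest.approx(
                _fisher_oracle(table), abs=1e-9)


class TestKruskal:
    def test_hand_ranked_example(self):
        h, df, p = kruskal_wallis([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
        assert h == pytest.approx(12 / 42 * 87 - 21)
        assert df == 1

    def test_rank_invariance_under_permutation(self, rng):
        values = rng.random(30)
        groups = rng.integers(0, 3, size=30)
        perm = rng.permutation(30)
        h1, _, _ = kruskal_wallis(values, groups)
        h2, _, _ = kruskal_wallis(values[perm], groups[perm])
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_identical_values_degenerate(self):
        h, df, p = kruskal_wallis([2.0] * 6, [0, 0, 0, 1, 1, 1])
        assert (h, p) == (0.0, 1.0)

    def test_matches_manual_tie_corrected_formula(self, rng):
        for _ in range(100):
            values = rng.integers(0, 8, size=40).astype(float)  # heavy ties
            groups = rng.integers(0, 3, size=40)
            if len(np.unique(groups)) < 2 or np.all(values == values[0]):
                continue
            ranks = sps.rankdata(values)
            n = len(values)
            num = sum(
                ranks[groups == g].sum() ** 2 / (groups == g).sum()
                for g in np.unique(groups)
            )
            h = 12 / (n * (n + 1)) * num - 3 * (n + 1)
            _, counts = np.unique(values, return_counts=True)
            tie = 1 - np.sum(counts**3 - counts) / (n**3 - n)
            h /= tie
            got, _, _ = kruskal_wallis(values, groups)
            assert got == pytest.approx(h, abs=1e-10)


def _auc_pairwise_oracle(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        auc, (lo, hi) = auc_with_ci([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0 and hi == 1.0

    def test_null_scores_near_half(self, rng):
        scores = rng.random(4000)
        labels = rng.integers(0, 2, size=4000)
        auc, (lo, hi) = auc_with_ci(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.03)
        assert lo <= 0.5 <= hi

    def test_one_class_absent_is_undefined(self):
        auc, (lo, hi) = auc_with_ci([0.1, 0.9], [1, 1])
        assert math.isnan(auc)

    def test_matches_pairwise_oracle_with_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 500))
            scores = rng.random(n).round(1)
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            auc, _ = auc_with_ci(scores, labels)
            assert auc == pytest.approx(
                _auc_pairwise_oracle(scores, labels), abs=1e-12)

    def test_identical_scores_compare_as_equal(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        chi2, p = compare_auc_paired(scores, scores, labels)
        assert (chi2, p) == (0.0, 1.0)

    def test_paired_comparison_is_symmetric(self, rng):
        n = 200
        labels = rng.integers(0, 2, size=n)
        labels[:2] = [0, 1]
        sa = rng.random(n) + 0.3 * labels
        sb = rng.random(n) + 0.1 * labels
        chi2_ab, p_ab = compare_auc_paired(sa, sb, labels)
        chi2_ba, p_ba = compare_auc_paired(sb, sa, labels)
        assert chi2_ab == pytest.approx(chi2_ba, rel=1e-12)
        assert chi2_ab > 0

    def test_delong_variance_close_to_bootstrap(self):
        rng = np.random.default_rng(7)
        n = 300
        labels = rng.integers(0, 2, size=n)
        labels[:2] = [0, 1]
        sa = rng.random(n) + 0.5 * labels
        sb = rng.random(n) + 0.3 * labels
        auc_a, _ = auc_with_ci(sa, labels)
        auc_b, _ = auc_with_ci(sb, labels)
        chi2, _ = compare_auc_paired(sa, sb, labels)
        var_delong = (auc_a - auc_b) ** 2 / chi2
        diffs = []
        for _ in range(2000):
            idx = rng.integers(0, n, size=n)
            yb = labels[idx]
            if len(np.unique(yb)) < 2:
                continue
            da, _ = auc_with_ci(sa[idx], yb)
            db, _ = auc_with_ci(sb[idx], yb)
            diffs.append(da - db)
        var_boot = np.var(diffs, ddof=1)
        assert var_delong == pytest.approx(var_boot, rel=0.25)


class TestLogSuvModels:
    def test_slope_equals_simple_least_squares_reference(self, default_cohort):
        fit = fit_log_suv_model(default_cohort, form="primary_covariance")
        recs = [r for r in default_cohort if r.truth_positive]
        y = np.log([r.suv_max for r in recs])
        X = sm.add_constant(np.column_stack([
            np.log([r.suv_max_primary for r in recs]),
            [r.echelon == 2 for r in recs],
            [r.echelon == 3 for r in recs],
        ]).astype(float))
        ref = sm.OLS(y, X).fit()
        assert fit.coefficients["log_suv_primary"] == pytest.approx(ref.params[1], abs=1e-10)
        assert fit.standard_errors["log_suv_primary"] == pytest.approx(ref.bse[1], rel=1e-8)

    def test_balanced_factor_f_equals_t_squared(self, default_cohort):
        fit = fit_log_suv_model(default_cohort, form="primary_covariance")
        # drop-term F for the 1-df slope term equals its Wald t^2
        t = fit.coefficients["log_suv_primary"] / fit.standard_errors["log_suv_primary"]
        f, df_num, df_den, p = fit.f_tests["log_suv_primary"]
        assert df_num == 1
        assert f == pytest.approx(t**2, rel=1e-8)

    def test_intra_patient_echelon_effect_detected(self, default_cohort):
        fit = fit_log_suv_model(default_cohort, form="intra_patient")
        f, df_num, df_den, p = fit.f_tests["echelon"]
        assert p < 0.01  # generator builds in a negative echelon gradient
        assert fit.coefficients["ech2"] < 0 and fit.coefficients["ech3"] < 0

    def test_echelon_offsets_recovered(self, default_cohort):
        fit = fit_log_suv_model(default_cohort, form="primary_covariance")
        assert fit.coefficients["ech2"] == pytest.approx(-0.328, abs=3 * fit.standard_errors["ech2"])
        assert fit.coefficients["ech3"] == pytest.approx(-0.422, abs=3 * fit.standard_errors["ech3"])

    def test_single_echelon_rejected(self):
        cohort = generate_cohort(CohortConfig(n_patients=30, seed=5))
        from petnode.core import Cohort
        only_e1 = Cohort(records=tuple(r for r in cohort if r.echelon == 1))
        with pytest.raises(ValueError):
            fit_log_suv_model(only_e1, form="primary_covariance")
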