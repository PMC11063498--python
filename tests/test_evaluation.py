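"""ROC/AUC, Youden cutoff, exact tests, group comparison, sample size."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from ipreface import (
    auc_sample_size,
    compare_groups,
    fisher_exact_2x2,
    roc_analysis,
    summarize_cohort,
    youden_cutoff,
)
from ipreface.evaluation import acidemia_rates, continuous_group_test
from ipreface.exceptions import AnalysisError, ComparisonError

from conftest import make_case, pair_count_auc


class TestROC:
    def test_perfect_separation(self):
        roc = roc_analysis([1, 2, 3, 4], [False, False, True, True])
        assert roc.auc == 1.0

    def test_all_tied_scores(self):
        roc = roc_analysis([5, 5, 5, 5], [False, True, False, True])
        assert roc.auc == 0.5

    def test_degenerate_outcomes_rejected(self):
        with pytest.raises(AnalysisError):
            roc_analysis([1, 2, 3], [True, True, True])

    def test_roc_points_monotone(self):
        rng = np.random.default_rng(3)
        s = rng.integers(0, 20, 60).astype(float)
        y = rng.random(60) < 0.3
        roc = roc_analysis(s, y)
        # sensitivity non-increasing as the threshold rises
        assert (np.diff(roc.sensitivity) <= 1e-12).all()
        assert roc.auc_ci_low <= roc.auc <= roc.auc_ci_high

    @given(st.integers(0, 10_000))
    def test_auc_equals_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 41))
        s = rng.integers(0, 12, n).astype(float)
        y = rng.random(n) < 0.4
        if 0 < y.sum() < n:
            roc = roc_analysis(s, y)
            assert roc.auc == pytest.approx(pair_count_auc(s, y), abs=1e-12)

    def test_delong_ci_covers_true_auc(self):
        """Normal-approximation CI coverage at n=113, 11 positives, over 1000
        replicates of a binormal model with true AUC 0.8.  Band [0.92, 0.98]
        allows the known mild small-sample anticonservatism of the
        normal-approximation interval at 11 positives."""
        true_auc = 0.8
        mu = np.sqrt(2) * stats.norm.ppf(true_auc)
        rng = np.random.default_rng(20240404)
        hits = 0
        reps = 1000
        for _ in range(reps):
            s = np.concatenate([rng.normal(0, 1, 102), rng.normal(mu, 1, 11)])
            y = np.concatenate([np.zeros(102, bool), np.ones(11, bool)])
            roc = roc_analysis(s, y)
            hits += roc.auc_ci_low <= true_auc <= roc.auc_ci_high
        assert 0.92 <= hits / reps <= 0.98


class TestYouden:
    def test_perfect_separation_cutoff(self):
        roc = roc_analysis([1, 2, 3, 4], [False, False, True, True])
        cut = youden_cutoff(roc)
        assert (cut.cutoff, cut.sensitivity, cut.specificity) == (3.0, 1.0, 1.0)
        assert cut.youden_j == 1.0
        assert cut.fpr == 0.0 and cut.fnr == 0.0

    @given(st.integers(0, 10_000))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 50))
        s = rng.integers(0, 15, n).astype(float)
        y = rng.random(n) < 0.35
        if not 0 < y.sum() < n:
            return
        cut = youden_cutoff(roc_analysis(s, y))
        # oracle: maximize J over every candidate threshold, smallest wins ties
        best_j, best_t = -2.0, None
        for t in sorted(set(s)) + [np.inf]:
            sens = np.mean(s[y] >= t)
            spec = np.mean(s[~y] < t)
            if sens + spec - 1 > best_j + 1e-12:
                best_j, best_t = sens + spec - 1, t
        assert cut.cutoff == best_t
        assert cut.youden_j == pytest.approx(best_j, abs=1e-12)

    def test_cutoff_recovery_on_sharp_generator(self):
        """Two binomial score distributions with a sharply peaked Youden curve
        (crossing at 20): the estimated cutoff lands within one score unit of
        the optimum in >= 90% of seeded replicates."""
        rng = np.random.default_rng(11)
        hits = 0
        reps = 100
        for _ in range(reps):
            neg = rng.binomial(40, 0.4, 200).astype(float)
            pos = rng.binomial(40, 0.6, 200).astype(float)
            s = np.concatenate([neg, pos])
            y = np.concatenate([np.zeros(200, bool), np.ones(200, bool)])
            cut = youden_cutoff(roc_analysis(s, y))
            hits += abs(cut.cutoff - 20.0) <= 1.0
        assert hits / reps >= 0.90


class TestFisher:
    def test_no_events_gives_p_one(self):
        assert fisher_exact_2x2(0, 10, 0, 20) == 1.0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)

    @given(st.integers(0, 10_000))
    def test_matches_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(0, 11, 4))
        if a + b + c + d == 0:
            return
        p = fisher_exact_2x2(a, b, c, d)
        n, r, col = a + b + c + d, a + b, a + c
        sup = np.arange(max(0, r + col - n), min(r, col) + 1)
        pmf = stats.hypergeom.pmf(sup, n, r, col)
        p_oracle = pmf[pmf <= pmf[sup == a][0] * (1 + 1e-9)].sum()
        assert p == pytest.approx(p_oracle, rel=1e-7)


class TestCompareGroups:
    @staticmethod
    def cohort(values_a, values_b, flag_a=None, flag_b=None):
        cases = []
        for i, v in enumerate(values_a):
            cases.append(make_case(f"A{i}", maternal_age=float(v)))
        for i, v in enumerate(values_b):
            cases.append(make_case(f"B{i}", maternal_age=float(v), vacuum=True))
        return cases

    def test_identical_values_give_p_one(self):
        cases = self.cohort([30.0] * 8, [30.0] * 8)
        rows = compare_groups(cases, lambda c: int(c.vacuum),
                              [("age", "continuous", lambda c: c.maternal_age)])
        assert rows[0].p_value == 1.0

    def test_proportion_rows_use_fisher_on_sparse_tables(self):
        # the sparse acidemia-style split routes through Fisher's exact test
        cases = ([make_case(f"P{i}", ph=7.10) for i in range(7)]
                 + [make_case(f"Q{i}", ph=7.30) for i in range(4)]
                 + [make_case(f"R{i}", ph=7.10) for i in range(3)]
                 + [make_case(f"S{i}", ph=7.30) for i in range(99)])
        group = lambda c: 0 if c.case_id[0] in "PQ" else 1
        rows = compare_groups(cases, group,
                              [("pH<7.2", "binary", lambda c: c.blood_gas.ph < 7.2)])
        assert rows[0].test == "fisher"
        assert rows[0].p_value == pytest.approx(fisher_exact_2x2(7, 4, 3, 99), rel=1e-9)

    def test_large_balanced_tables_use_chi_square(self):
        cases = ([make_case(f"A{i}", vacuum=i % 2 == 0) for i in range(40)]
                 + [make_case(f"B{i}", vacuum=i % 3 == 0, ph=7.1) for i in range(40)])
        rows = compare_groups(cases, lambda c: int(c.blood_gas.ph < 7.2),
                              [("vacuum", "binary", lambda c: c.vacuum)])
        assert rows[0].test == "chi-square"

    def test_three_groups_use_omnibus_tests(self):
        rng = np.random.default_rng(0)
        cases = [make_case(f"G{g}_{i}", maternal_age=float(rng.normal(30 + g, 2)),
                           parity=g) for g in range(3) for i in range(15)]
        rows = compare_groups(cases, lambda c: c.parity,
                              [("age", "continuous", lambda c: c.maternal_age)])
        assert rows[0].test in ("anova", "kruskal-wallis")
        assert rows[0].p_value < 0.05

    def test_single_group_rejected(self):
        cases = [make_case(f"A{i}") for i in range(5)]
        with pytest.raises(ComparisonError):
            compare_groups(cases, lambda c: 0,
                           [("age", "continuous", lambda c: c.maternal_age)])

    def test_skewed_data_routes_to_rank_test(self):
        rng = np.random.default_rng(1)
        cases = ([make_case(f"A{i}", maternal_age=float(np.exp(rng.normal(2.0, 0.9))))
                  for i in range(40)]
                 + [make_case(f"B{i}", maternal_age=float(np.exp(rng.normal(2.4, 0.9))),
                              vacuum=True) for i in range(40)])
        rows = compare_groups(cases, lambda c: int(c.vacuum),
                              [("age", "continuous", lambda c: c.maternal_age)])
        assert rows[0].test == "mann-whitney"


class TestSampleSize:
    def test_published_design_gives_80(self):
        assert auc_sample_size(0.80, 0.90, 0.05, 9) == (8, 72, 80)

    def test_total_nonincreasing_in_auc(self):
        totals = [auc_sample_size(a, 0.90, 0.05, 9)[2]
                  for a in (0.65, 0.70, 0.80, 0.90, 0.95)]
        assert totals == sorted(totals, reverse=True)

    @pytest.mark.parametrize("bad", [0.5, 0.45])
    def test_null_or_worse_auc_rejected(self, bad):
        with pytest.raises(ValueError):
            auc_sample_size(bad)

    def test_matches_monte_carlo_power_oracle(self):
        """The analytic positive count agrees within +/-1 with the smallest
        count whose simulated one-sided test power reaches 0.90 (binormal
        scores with AUC 0.80, 10^4 replicates per candidate count)."""
        n_pos, _, _ = auc_sample_size(0.80, 0.90, 0.05, 9)
        mu = np.sqrt(2) * stats.norm.ppf(0.80)
        z_a = stats.norm.ppf(0.95)

        def v0(m, n):
            # null-variance of the Mann-Whitney AUC at A=0.5
            return (0.25 + (m - 1) / 12 + (n - 1) / 12) / (m * n)

        rng = np.random.default_rng(7)
        mc_m = None
        for m in range(2, 30):
            n = 9 * m
            pos = rng.normal(mu, 1, (10_000, m))
            neg = rng.normal(0, 1, (10_000, n))
            auc = (pos[:, :, None] > neg[:, None, :]).mean(axis=(1, 2))
            power = np.mean((auc - 0.5) / np.sqrt(v0(m, n)) > z_a)
            if power >= 0.90:
                mc_m = m
                break
        assert mc_m is not None
        assert abs(n_pos - mc_m) <= 1


class TestCohortSummary:
    def test_single_case_echoes_its_values(self):
        df = summarize_cohort([make_case(ph=7.25)])
        assert df.loc["n", "all"] == "1"
        assert df.loc["pH < 7.2", "all"] == "0.0 (0/1)"

    def test_acidemia_rates_are_nested(self):
        rng = np.random.default_rng(2)
        cases = [make_case(f"C{i}", ph=float(np.clip(rng.normal(7.25, 0.12), 6.8, 7.5)))
                 for i in range(60)]
        rates = acidemia_rates(cases)
        assert rates[7.0] <= rates[7.1] <= rates[7.2]

    def test_table_shaped_prevalence(self):
        # 113-case fixture with exactly 11 below pH 7.2 reports a 9.7% rate
        cases = ([make_case(f"L{i}", ph=7.10) for i in range(11)]
                 + [make_case(f"H{i}", ph=7.32) for i in range(102)])
        df = summarize_cohort(cases)
        assert df.loc["pH < 7.2", "all"] == "9.7 (11/113)"

    def test_empty_cohort_rejected(self):
        with pytest.raises(ComparisonError):
            summarize_cohort([])


def test_continuous_selection_rule_prefers_t_on_normal_data():
    rng = np.random.default_rng(4)
    name, _ = continuous_group_test([rng.normal(0, 1, 40), rng.normal(0, 1, 40)])
    assert name == "t"
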