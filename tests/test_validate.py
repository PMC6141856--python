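import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coexnet import (
    SurvivalTable,
    gene_pair_correlation,
    kaplan_meier,
    logrank_test,
    median_split,
    oneway_anova,
    roc_auc,
    two_group_ttest,
)


def _surv(times, events, samples=None):
    samples = samples or [f"s{i}" for i in range(len(times))]
    return SurvivalTable(pd.DataFrame({"time": times, "event": events}, index=samples))


class TestMedianSplit:
    def test_even_split(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        g = median_split(s)
        assert (g == "high").sum() == 2
        assert g["c"] == "high" and g["b"] == "low"

    def test_all_identical_go_low(self):
        s = pd.Series([5.0] * 6, index=[f"s{i}" for i in range(6)])
        assert (median_split(s) == "low").all()

    def test_odd_n_low_has_ceiling(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde"))
        assert (median_split(s) == "low").sum() == 3


class TestKaplanMeier:
    def test_all_censored_survival_is_one(self):
        curves = kaplan_meier(_surv([1.0, 2.0, 3.0], [0, 0, 0]))
        assert np.allclose(curves["all"].survival, 1.0)

    def test_three_events_closed_form(self):
        curves = kaplan_meier(_surv([1.0, 2.0, 3.0], [1, 1, 1]))
        assert np.allclose(curves["all"].survival, [2 / 3, 1 / 3, 0.0])
        assert np.array_equal(curves["all"].at_risk, [3, 2, 1])

    def test_matches_risk_table_oracle(self, rng):
        times = rng.exponential(5.0, 20).round(1)
        events = rng.integers(0, 2, 20)
        curves = kaplan_meier(_surv(times, events))
        c = curves["all"]
        # oracle: explicit product-limit over the risk table
        s = 1.0
        expected = []
        for t in c.times:
            n = (times >= t).sum()
            d = ((times == t) & (events == 1)).sum()
            s *= 1 - d / n
            expected.append(s)
        assert np.allclose(c.survival, expected, atol=1e-12)
        assert np.all(np.diff(c.survival) <= 1e-12)  # non-increasing

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(3.0, 25)
        curves = kaplan_meier(_surv(times, np.ones(25, dtype=int)))
        c = curves["all"]
        emp = [(times > t).mean() for t in c.times]
        assert np.allclose(c.survival, emp, atol=1e-12)

    def test_grouped_curves(self):
        groups = pd.Series(["a", "a", "b", "b"], index=[f"s{i}" for i in range(4)])
        curves = kaplan_meier(_surv([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1]), groups)
        assert set(curves) == {"a", "b"}
        assert np.allclose(curves["a"].survival, [0.5, 0.0])


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        times = [1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0]
        events = [1, 1, 0, 1] * 2
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=[f"s{i}" for i in range(8)])
        res = logrank_test(_surv(times, events), groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_worked_12_subject_table_matches_enumeration_oracle(self, rng):
        times = np.array([2.0, 3.0, 3.0, 5.0, 6.0, 7.0, 1.0, 4.0, 4.0, 8.0, 9.0, 9.0])
        events = np.array([1, 1, 0, 1, 1, 0, 1, 1, 1, 0, 1, 1])
        groups = pd.Series(["x"] * 6 + ["y"] * 6, index=[f"s{i}" for i in range(12)])
        res = logrank_test(_surv(times, events), groups)
        # oracle: explicit O/E/V enumeration over distinct event times
        gx = np.array([True] * 6 + [False] * 6)
        o1 = e1 = v = 0.0
        for t in sorted(set(times[events == 1])):
            n = (times >= t).sum()
            n1 = (times[gx] >= t).sum()
            d = ((times == t) & (events == 1)).sum()
            d1 = ((times == t) & (events == 1) & gx).sum()
            o1 += d1
            e1 += d * n1 / n
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        from scipy.stats import chi2

        assert res.statistic == pytest.approx((o1 - e1) ** 2 / v, abs=1e-12)
        assert res.p_value == pytest.approx(chi2.sf((o1 - e1) ** 2 / v, 1), abs=1e-12)
        assert sum(res.observed.values()) == pytest.approx(sum(res.expected.values()))

    def test_agrees_with_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        times = rng.exponential(5.0, 40)
        events = rng.integers(0, 2, 40)
        gmask = rng.integers(0, 2, 40).astype(bool)
        groups = pd.Series(np.where(gmask, "a", "b"), index=[f"s{i}" for i in range(40)])
        res = logrank_test(_surv(times, events), groups)
        ll = ll_logrank(times[gmask], times[~gmask], events[gmask], events[~gmask])
        assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ll.p_value, rel=1e-9)

    def test_group_relabeling_invariance(self, rng):
        times = rng.exponential(4.0, 30)
        events = rng.integers(0, 2, 30)
        lab = rng.integers(0, 2, 30)
        idx = [f"s{i}" for i in range(30)]
        g1 = pd.Series(np.where(lab == 1, "high", "low"), index=idx)
        g2 = pd.Series(np.where(lab == 1, "low", "high"), index=idx)
        r1 = logrank_test(_surv(times, events, idx), g1)
        r2 = logrank_test(_surv(times, events, idx), g2)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)

    def test_single_group_errors(self):
        groups = pd.Series(["a"] * 4, index=[f"s{i}" for i in range(4)])
        with pytest.raises(ValueError, match="2"):
            logrank_test(_surv([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1]), groups)

    def test_strong_simulated_effect_detected(self):
        from coexnet import SimulationConfig, simulate_expression, simulate_survival

        detected = 0
        for seed in range(100):
            cfg = SimulationConfig(
                module_sizes=(10,), n_background_genes=5, n_samples=100, trait_module_index=0,
                survival_log_hazard_coef=2.0, seed=seed,
            )
            expr, _, truth = simulate_expression(cfg)
            surv = simulate_survival(expr, truth, cfg)
            groups = median_split(expr.data.loc[truth.survival_gene])
            if logrank_test(surv, groups).p_value < 0.05:
                detected += 1
        assert detected >= 95


class TestROC:
    def test_perfect_separation(self):
        res = roc_auc([1.0, 2.0, 3.0, 10.0, 11.0, 12.0], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert (res.fpr[0], res.tpr[0]) == (0.0, 0.0)
        assert (res.fpr[-1], res.tpr[-1]) == (1.0, 1.0)

    def test_all_tied_scores_auc_half(self):
        res = roc_auc([5.0] * 8, [0, 1, 0, 1, 0, 1, 0, 1])
        assert res.auc == pytest.approx(0.5)

    def test_matches_pair_counting_oracle(self, rng):
        scores = rng.normal(size=30).round(1)  # rounding forces some ties
        labels = rng.integers(0, 2, 30)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(0, 2, 30)
        res = roc_auc(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert res.auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="2 classes"):
            roc_auc([1.0, 2.0], [1, 1])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_score_negation_flips_auc(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=20)  # continuous, so tie-free a.s.
        labels = np.array([0] * 10 + [1] * 10)
        a1 = roc_auc(scores, labels).auc
        a2 = roc_auc(-scores, labels).auc
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)


class TestTTestAnova:
    def test_identical_groups_t_zero(self):
        v = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = np.array(["a"] * 3 + ["b"] * 3)
        t, df, p = two_group_ttest(v, labels)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_large_shift_tiny_p(self):
        v = np.array([1.0, 2.0, 3.0, 11.0, 12.0, 13.0])
        labels = np.array(["a"] * 3 + ["b"] * 3)
        _, _, p = two_group_ttest(v, labels)
        assert p < 1e-3

    def test_welch_matches_formula_oracle(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 2, 12)
        t, df, p = two_group_ttest(np.r_[a, b], np.array(["a"] * 10 + ["b"] * 12))
        va, vb = a.var(ddof=1) / 10, b.var(ddof=1) / 12
        t_o = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_o = (va + vb) ** 2 / (va**2 / 9 + vb**2 / 11)
        from scipy.stats import t as tdist

        assert t == pytest.approx(t_o, abs=1e-10)
        assert df == pytest.approx(df_o, abs=1e-10)
        assert p == pytest.approx(2 * tdist.sf(abs(t_o), df_o), abs=1e-10)

    def test_small_group_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            two_group_ttest(np.array([1.0, 2.0, 3.0]), np.array(["a", "b", "b"]))

    def test_anova_two_levels_equals_pooled_t_squared(self, rng):
        v = rng.normal(size=14)
        labels = np.array(["a"] * 6 + ["b"] * 8)
        F, (df1, df2), p_f = oneway_anova(v, labels)
        t, df, p_t = two_group_ttest(v, labels, equal_var=True)
        assert F == pytest.approx(t**2, abs=1e-10)
        assert p_f == pytest.approx(p_t, abs=1e-10)

    def test_anova_matches_sum_of_squares_oracle(self, rng):
        v = rng.normal(size=18)
        labels = np.repeat(["a", "b", "c"], 6)
        F, (df1, df2), p = oneway_anova(v, labels)
        grand = v.mean()
        groups = [v[labels == g] for g in "abc"]
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        from scipy.stats import f

        F_o = (ssb / 2) / (ssw / 15)
        assert F == pytest.approx(F_o, abs=1e-10)
        assert (df1, df2) == (2, 15)
        assert p == pytest.approx(f.sf(F_o, 2, 15), abs=1e-10)
        from scipy.stats import f_oneway

        assert F == pytest.approx(f_oneway(*groups).statistic, abs=1e-10)

    def test_anova_degenerate_all_equal(self):
        with pytest.warns(UserWarning, match="degenerate"):
            F, _, p = oneway_anova(np.full(6, 2.0), np.repeat(["a", "b"], 3))
        assert F == 0.0 and p == 1.0

    def test_anova_small_level_errors(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            oneway_anova(np.array([1.0, 2.0, 3.0]), np.array(["a", "a", "b"]))


class TestGenePairCorrelation:
    def test_self_correlation_is_one(self, small_expr):
        r, p = gene_pair_correlation(small_expr, ["g00", "g01"])
        assert r.loc["g00", "g00"] == pytest.approx(1.0, abs=1e-12)

    def test_shares_kernel_with_adjacency(self, small_expr):
        from coexnet import adjacency

        genes = small_expr.gene_ids[:4]
        r, _ = gene_pair_correlation(small_expr, genes)
        adj = adjacency(small_expr.subset_genes(genes), power=1)
        assert np.allclose(np.abs(r.to_numpy()) - np.eye(4), adj.matrix, atol=1e-15)

    def test_independent_genes_null_p_uniform(self):
        from scipy.stats import kstest

        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x, y = rng.normal(size=20), rng.normal(size=20)
            em = pd.DataFrame([x, y], index=["a", "b"], columns=[f"s{i}" for i in range(20)])
            from coexnet import ExpressionMatrix

            r, p = gene_pair_correlation(ExpressionMatrix(em), ["a", "b"])
            pvals.append(p.loc["a", "b"])
        assert kstest(pvals, "uniform").pvalue > 0.01
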