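"""Rank statistics, survival stratification and cohort screens."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cernanet.cohort import (
    CohortDataset,
    correlation_screen,
    kruskal_dunn,
    logrank_test,
    median_split,
    rank_sum_test,
    spearman,
    summarize_target_table,
    survival_screen,
)
from cernanet.config import SyntheticConfig
from cernanet.synthetic import generate_cohort


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p, n = spearman([1, 2, 3, 4], [2, 4, 6, 8])
        assert rho == pytest.approx(1.0)
        assert p > 0  # numerical floor, never exactly zero
        assert n == 4

    def test_rank_formula_value(self):
        # d = (0, 1, 1, -1, 1): sum d^2 = 4... recompute: ranks equal values
        # here; x=(1..5), y=(3,1,2,5,4): d=(-2,1,1,-1,1), sum d^2 = 8
        rho, _, _ = spearman([1, 2, 3, 4, 5], [3, 1, 2, 5, 4])
        assert rho == pytest.approx(1 - 6 * 8 / (5 * 24))
        assert rho == pytest.approx(0.6)

    def test_perfect_antimonotone(self):
        rho, _, _ = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_formula_on_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            n = int(rng.integers(5, 40))
            x = rng.permutation(n).astype(float)  # distinct values: no ties
            y = rng.permutation(n).astype(float)
            rho, _, _ = spearman(x, y)
            d = stats.rankdata(x) - stats.rankdata(y)
            expected = 1 - 6 * (d**2).sum() / (n * (n**2 - 1))
            assert rho == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        rho0, p0, _ = spearman(x, y)
        rho1, p1, _ = spearman(np.exp(x), y**3 + 5 * y)
        assert rho1 == pytest.approx(rho0, abs=1e-12)
        assert p1 == pytest.approx(p0, abs=1e-12)

    def test_pairwise_complete_and_minimum_n(self):
        x = [1, 2, 3, 4, np.nan]
        y = [2, 1, 4, 3, 9]
        _, _, n = spearman(x, y)
        assert n == 4
        with pytest.raises(ValueError, match="at least 4"):
            spearman([1, 2, np.nan, np.nan], [1, 2, 3, 4])

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestRankSum:
    def test_extreme_separation(self):
        w, p, direction = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert w == 6  # minimum possible rank sum for n=3
        assert direction == "b"

    def test_identical_multisets(self):
        _, p, direction = rank_sum_test([1, 2, 2, 3], [1, 2, 2, 3])
        assert p >= 0.99
        assert direction == "tie"

    def test_all_identical_raises(self):
        with pytest.raises(ValueError, match="identical"):
            rank_sum_test([5, 5], [5, 5])

    def test_power_under_planted_shift(self):
        rng = np.random.default_rng(100)
        hits = 0
        for _ in range(100):
            a = rng.normal(0, 1, 50)
            b = rng.normal(1.5, 1, 50)
            _, p, direction = rank_sum_test(a, b)
            hits += p < 0.01 and direction == "b"
        assert hits >= 95

    def test_null_p_approximately_uniform(self):
        rng = np.random.default_rng(200)
        pvals = []
        for _ in range(500):
            pooled = rng.normal(size=60)
            _, p, _ = rank_sum_test(pooled[:30], pooled[30:])
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.1


class TestKruskalDunn:
    def test_equal_mean_ranks_give_zero_h(self):
        # three interleaved groups of 1..9 with equal rank sums
        g = [[1, 6, 8], [2, 4, 9], [3, 5, 7]]
        h, p, _ = kruskal_dunn(g)
        assert h == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_groups_match_rank_sum_squared_z(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            a = np.round(rng.normal(size=25), 1)  # rounding induces ties
            b = np.round(rng.normal(0.3, 1, size=20), 1)
            _, p_kw, _ = kruskal_dunn([a, b])
            _, p_rs, _ = rank_sum_test(a, b)
            assert p_kw == pytest.approx(p_rs, abs=1e-9)

    def test_power_with_one_shifted_group(self):
        rng = np.random.default_rng(77)
        hits = 0
        for _ in range(100):
            groups = [rng.normal(0, 1, 40), rng.normal(0, 1, 40),
                      rng.normal(1.0, 1, 40)]
            _, p, _ = kruskal_dunn(groups)
            hits += p < 0.05
        assert hits >= 90

    def test_dunn_pairwise_table_and_bh(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(0, 1, 30), rng.normal(0, 1, 30),
                  rng.normal(2, 1, 30)]
        _, _, table = kruskal_dunn(groups, adjust="bh")
        assert len(table) == 3
        assert (table["p_adj"] >= table["p"] - 1e-15).all()
        # the shifted group should separate from both others
        sig = table[(table["group_j"] == 2) | (table["group_i"] == 2)]
        assert (sig["p_adj"] < 0.05).all()

    def test_fewer_than_two_groups_raises(self):
        with pytest.raises(ValueError):
            kruskal_dunn([[1, 2, 3]])


class TestMedianSplit:
    def test_even_split_distinct_values(self):
        labels = median_split([1, 2, 3, 4])
        assert list(labels) == ["low", "low", "high", "high"]

    def test_tie_goes_low(self):
        labels = median_split([1, 2, 2, 3])
        assert list(labels) == ["low", "low", "low", "high"]

    def test_constant_values_raise(self):
        with pytest.raises(ValueError):
            median_split([5, 5, 5, 5])

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.integers(min_value=-50, max_value=50),
                    min_size=4, max_size=60))
    def test_partition_properties(self, values):
        v = np.asarray(values, dtype=float)
        try:
            labels = median_split(v)
        except ValueError:
            # the high stratum is empty iff no value exceeds the median
            assert v.max() <= np.median(v)
            return
        med = np.median(v)
        assert set(labels) == {"low", "high"}
        assert (v[labels == "low"] <= med).all()
        assert (v[labels == "high"] > med).all()

    def test_group_size_imbalance_bounded_by_median_ties(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            v = rng.integers(0, 10, size=int(rng.integers(4, 50))).astype(float)
            try:
                labels = median_split(v)
            except ValueError:
                continue
            n_low = (labels == "low").sum()
            n_high = (labels == "high").sum()
            n_tied = (v == np.median(v)).sum()
            # the <=-median rule sends every value tied at the median to the
            # low stratum, so each tie can widen the gap by at most two
            assert abs(n_low - n_high) <= max(2 * n_tied, 1)
            if n_tied == 0:
                assert n_low == n_high


class TestLogrank:
    def test_identical_groups_give_null(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        labels = ["low"] * 4 + ["high"] * 4
        chi2, p = logrank_test(times, events, labels)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_worked_hypergeometric_sums(self):
        # group A events at t=1,2; group B events at t=3,4; no censoring
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 1, 1])
        labels = np.array(["A", "A", "B", "B"])
        # hand-summed 2x2 tables over distinct event times
        o_a, e_a, v = 0.0, 0.0, 0.0
        for t in sorted(set(times)):
            at_risk = times >= t
            d = int(((times == t) & (events == 1)).sum())
            n = int(at_risk.sum())
            n_a = int((at_risk & (labels == "A")).sum())
            o_a += int(((times == t) & (events == 1) & (labels == "A")).sum())
            e_a += d * n_a / n
            if n > 1:
                v += d * (n - d) * n_a * (n - n_a) / (n**2 * (n - 1))
        expected_chi2 = (o_a - e_a) ** 2 / v
        chi2, p = logrank_test(times, events, labels)
        assert chi2 == pytest.approx(expected_chi2, abs=1e-9)
        assert p == pytest.approx(stats.chi2.sf(expected_chi2, 1), abs=1e-9)

    def test_label_symmetric(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(10, 40)
        events = rng.integers(0, 2, 40)
        events[0] = 1
        labels = np.array(["low"] * 20 + ["high"] * 20)
        a = logrank_test(times, events, labels)
        b = logrank_test(times, events, np.where(labels == "low", "high", "low"))
        assert a == pytest.approx(b)

    def test_zero_events_raise(self):
        with pytest.raises(ValueError, match="events"):
            logrank_test([1, 2, 3, 4], [0, 0, 0, 0], ["low", "low", "high", "high"])

    def test_power_at_cohort_scale(self):
        # hazard ratio 2.5 between median-split groups, ~30% censoring
        rng = np.random.default_rng(55)
        lam = np.log(2) / 60
        horizon = -np.log(0.3) / lam
        hits = 0
        for _ in range(100):
            t_lo = rng.exponential(1 / lam, 375)
            t_hi = rng.exponential(1 / (lam * 2.5), 375)
            t = np.concatenate([t_lo, t_hi])
            events = (t <= horizon).astype(int)
            t = np.minimum(t, horizon)
            labels = np.array(["low"] * 375 + ["high"] * 375)
            _, p = logrank_test(t, events, labels)
            hits += p < 0.001
        assert hits >= 95

    def test_null_p_approximately_uniform(self):
        rng = np.random.default_rng(66)
        pvals = []
        for _ in range(500):
            t = rng.exponential(10, 40)
            events = (t <= 15).astype(int)
            t = np.minimum(t, 15)
            labels = rng.permutation(["low"] * 20 + ["high"] * 20)
            if events.sum() == 0:
                continue
            _, p = logrank_test(t, events, labels)
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.1


class TestCorrelationScreen:
    def test_driver_against_itself(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(
            rng.normal(size=(2, 30)),
            index=["NEAT1", "G1"],
            columns=[f"p{i}" for i in range(30)],
        )
        res = correlation_screen(CohortDataset(expr), "NEAT1", ["NEAT1"])
        assert res.table.loc["NEAT1", "rho"] == pytest.approx(1.0)
        assert bool(res.table.loc["NEAT1", "significant_positive"])

    def test_missing_target_reported_not_raised(self, caplog):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(
            rng.normal(size=(2, 30)),
            index=["NEAT1", "G1"],
            columns=[f"p{i}" for i in range(30)],
        )
        with caplog.at_level("WARNING"):
            res = correlation_screen(CohortDataset(expr), "NEAT1", ["G1", "GHOST"])
        assert np.isnan(res.table.loc["GHOST", "rho"])
        assert "GHOST" in caplog.text

    def test_planted_rho_recovery_large_cohort(self):
        # 13 planted genes at rho 0.4, n=774: every one flagged, estimates
        # close to the planted value, across repeated seeds
        recalls, errors = [], []
        for seed in range(5):
            cfg = SyntheticConfig(cohort_n=774, rho_planted=0.4, seed=seed)
            targets = [f"G{i:05d}" for i in range(40)]
            planted = targets[:13]
            cohort = generate_cohort(cfg, targets, planted_correlated=planted)
            res = correlation_screen(cohort, "NEAT1", targets)
            flagged = set(res.significant_positive)
            recalls.append(len(flagged & set(planted)) / 13)
            errors.extend(abs(res.table.loc[g, "rho"] - 0.4) for g in planted)
        assert np.mean(recalls) >= 0.95
        assert max(errors) < 0.1

    def test_null_false_positive_rate_half_alpha(self):
        # two-sided p with a positive-sign constraint: expected FPR ~ alpha/2
        cfg = SyntheticConfig(cohort_n=200, rho_planted=0.0, seed=5)
        targets = [f"G{i:05d}" for i in range(2000)]
        cohort = generate_cohort(cfg, targets)
        res = correlation_screen(cohort, "NEAT1", targets, alpha=0.05)
        fpr = len(res.significant_positive) / len(targets)
        assert fpr == pytest.approx(0.025, abs=0.012)


class TestSurvivalScreen:
    def make_cohort(self, seed=0, hr=2.5, n=400, n_planted=3, n_null=5):
        cfg = SyntheticConfig(cohort_n=n, hr_planted=hr, seed=seed)
        targets = [f"G{i:05d}" for i in range(n_planted + n_null)]
        return (
            generate_cohort(cfg, targets, planted_prognostic=targets[:n_planted]),
            targets[:n_planted],
            targets[n_planted:],
        )

    def test_planted_prognostic_recovery(self):
        cohort, planted, _ = self.make_cohort()
        res = survival_screen(cohort, planted)
        assert (res.table.loc[planted, "os_p"] < 0.05).all()
        assert res.table.loc[planted, "os_high_worse"].all()

    def test_all_censored_records_error(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            rng.normal(size=(1, 20)), index=["G1"],
            columns=[f"p{i}" for i in range(20)],
        )
        surv = pd.DataFrame(
            {"os_time": np.arange(20) + 1.0, "os_event": 0,
             "pfs_time": np.arange(20) + 1.0, "pfs_event": 0},
            index=expr.columns,
        )
        res = survival_screen(CohortDataset(expr, survival=surv), ["G1"])
        assert np.isnan(res.table.loc["G1", "os_p"])
        assert "events" in res.table.loc["G1", "note"]

    def test_replication_keeps_direction_and_sharpens_p(self):
        cohort, planted, _ = self.make_cohort(n=120)
        res1 = survival_screen(cohort, planted)
        doubled = CohortDataset(
            pd.concat([cohort.expr, cohort.expr.add_suffix("_dup")], axis=1),
            survival=pd.concat(
                [cohort.survival, cohort.survival.set_axis(
                    [f"{i}_dup" for i in cohort.survival.index])]
            ),
        )
        res2 = survival_screen(doubled, planted)
        for g in planted:
            assert res2.table.loc[g, "os_high_worse"] == \
                res1.table.loc[g, "os_high_worse"]
            assert res2.table.loc[g, "os_p"] <= res1.table.loc[g, "os_p"]


class TestSummarizeTargetTable:
    def test_empty(self):
        surv = pd.DataFrame(columns=["os_p", "pfs_p"])
        assert summarize_target_table(pd.Series(dtype=bool), surv) == (0, 0, 0)

    def test_single_pfs_only_gene(self):
        surv = pd.DataFrame({"os_p": [np.nan], "pfs_p": [0.01]}, index=["APBB1IP"])
        assert summarize_target_table(pd.Series([False]), surv) == (0, 0, 1)

    def test_counts_from_screen_result(self):
        cohort, planted, nulls = TestSurvivalScreen().make_cohort()
        res = survival_screen(cohort, planted + nulls)
        n_up, n_both, n_any = summarize_target_table(
            pd.Series(False, index=planted + nulls), res
        )
        assert n_up == 0
        assert n_both >= len(planted) - 1
        assert n_any >= n_both
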