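"""Median splits, separation groups, nonparametric tests and survival."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from munix_d50.cohort_stats import (
    MedianSplit,
    kaplan_meier,
    kruskal_wallis_bonferroni,
    log_rank,
    median_split,
    separation_classify,
    spearman,
    summarize_cohort,
)


def kruskal_h_by_hand(groups):
    """Independent rank-based oracle for the tie-free case."""
    pooled = np.concatenate(groups)
    ranks = pooled.argsort().argsort() + 1.0
    n = len(pooled)
    h, start = 0.0, 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)


def logrank_by_hand(times_a, times_b):
    """Observed-minus-expected tabulation over the pooled event grid
    (no censoring)."""
    grid = sorted(set(times_a) | set(times_b))
    o_minus_e, var = 0.0, 0.0
    for t in grid:
        na = sum(1 for x in times_a if x >= t)
        nb = sum(1 for x in times_b if x >= t)
        d = sum(1 for x in times_a if x == t) + sum(1 for x in times_b if x == t)
        oa = sum(1 for x in times_a if x == t)
        n = na + nb
        e = d * na / n
        o_minus_e += oa - e
        if n > 1:
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestMedianSplit:
    def test_even_cohort(self):
        split = median_split({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        assert split.cutoff == pytest.approx(2.5)
        assert {k for k, v in split.assignment.items() if v == "low"} == {"a", "b"}

    def test_tie_at_cutoff_goes_high(self):
        split = median_split({"a": 1.0, "b": 2.0, "c": 3.0})
        assert split.assignment["b"] == "high"

    def test_all_equal_is_degenerate_all_high(self):
        split = median_split({"a": 5.0, "b": 5.0, "c": 5.0})
        assert split.degenerate
        assert set(split.assignment.values()) == {"high"}

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            median_split({"a": 1.0, "b": float("nan")})

    @given(
        st.dictionaries(
            st.text(min_size=1, max_size=4),
            st.floats(0.1, 100),
            min_size=2,
            max_size=30,
        )
    )
    def test_partition_exhaustive_and_disjoint(self, values):
        split = median_split(values)
        assert set(split.assignment) == set(values)
        for k, v in values.items():
            assert split.assignment[k] == ("low" if v < split.cutoff else "high")


class TestSeparation:
    def test_all_quadrants(self):
        m50 = MedianSplit(1.0, {"a": "low", "b": "low", "c": "high", "d": "high"})
        d50 = MedianSplit(1.0, {"a": "low", "b": "high", "c": "low", "d": "high"})
        labels = separation_classify(m50, d50)
        assert labels == {
            "a": "same",
            "b": "low_m50_high_d50",
            "c": "high_m50_low_d50",
            "d": "same",
        }

    def test_mismatched_patients_rejected(self):
        with pytest.raises(ValueError):
            separation_classify(
                MedianSplit(1.0, {"a": "low"}), MedianSplit(1.0, {"b": "low"})
            )


class TestKruskalWallis:
    def test_identical_groups(self):
        omnibus, pairwise = kruskal_wallis_bonferroni(
            {"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]}
        )
        assert omnibus.statistic == 0.0 and omnibus.p == 1.0

    def test_fully_separated_groups_match_hand_rank_computation(self):
        groups = {
            "a": np.arange(1.0, 6.0),
            "b": np.arange(11.0, 16.0),
            "c": np.arange(21.0, 26.0),
        }
        omnibus, _ = kruskal_wallis_bonferroni(groups)
        assert omnibus.statistic == pytest.approx(
            kruskal_h_by_hand(list(groups.values()))
        )

    def test_bonferroni_caps_at_one(self):
        rng = np.random.default_rng(0)
        groups = {k: rng.normal(0, 1, 20) for k in "abc"}
        _, pairwise = kruskal_wallis_bonferroni(groups)
        for t in pairwise.values():
            assert t.p_adjusted == pytest.approx(min(1.0, 3 * t.p))
            assert t.p_adjusted >= t.p

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        groups = {k: rng.uniform(1, 10, 8) for k in "abc"}
        h0, _ = kruskal_wallis_bonferroni(groups)
        h1, _ = kruskal_wallis_bonferroni({k: np.exp(v) for k, v in groups.items()})
        assert h1.statistic == pytest.approx(h0.statistic)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis_bonferroni({"a": [1.0], "b": []})


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).statistic == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [40, 30, 20, 10]).statistic == pytest.approx(-1.0)

    def test_hand_rank_value(self):
        # ranks differ by d = (-1, 1, -1, 1, 0): r = 1 - 6*4/120 = 0.8
        assert spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]).statistic == pytest.approx(0.8)

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=25)
        assert spearman(x, x).statistic == pytest.approx(1.0)

    def test_undefined_pairs_dropped_and_min_n(self):
        with pytest.raises(ValueError):
            spearman([1.0, 2.0, np.nan], [1.0, 2.0, 3.0])


class TestKaplanMeier:
    def test_no_censoring_matches_empirical_survivor_function(self):
        times = [2.0, 4.0, 6.0, 8.0, 10.0]
        km = kaplan_meier(times, [True] * 5)
        for t, s in zip(km.times, km.survival):
            assert s == pytest.approx(np.mean(np.asarray(times) > t))

    def test_median_of_five_events(self):
        km = kaplan_meier([1, 2, 3, 4, 5], [True] * 5)
        assert km.median == 3.0

    def test_all_censored_median_undefined(self):
        km = kaplan_meier([1, 2, 3], [False] * 3)
        assert np.isnan(km.median)

    def test_single_subject(self):
        km = kaplan_meier([5.0], [True])
        assert km.median == 5.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        t, e = [1.0, 2.0, 3.0], [True, True, False]
        res = log_rank(t, e, t, e)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_hand_computation_on_separated_groups(self):
        a, b = [1.0, 2.0, 3.0], [10.0, 20.0, 30.0]
        res = log_rank(a, [True] * 3, b, [True] * 3)
        assert res.statistic == pytest.approx(logrank_by_hand(a, b))

    def test_symmetric_under_label_swap(self):
        rng = np.random.default_rng(5)
        ta, tb = rng.exponential(20, 15), rng.exponential(35, 12)
        ea, eb = rng.uniform(size=15) < 0.8, rng.uniform(size=12) < 0.8
        r1 = log_rank(ta, ea, tb, eb)
        r2 = log_rank(tb, eb, ta, ea)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p == pytest.approx(r2.p)

    def test_one_group_without_events_flagged_degenerate(self):
        res = log_rank([1.0, 2.0], [True, True], [3.0, 4.0], [False, False])
        assert res.degenerate


class TestSummarize:
    @staticmethod
    def tables(n=1):
        fits = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "d50": [25.0 + i for i in range(n)],
                "dx": [6.0] * n,
                "subgroup": ["intermediate"] * n,
                "rd50_at_munix": [0.3] * n,
                "converged": [True] * n,
                "identifiable": [True] * n,
            }
        )
        metrics = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "m50": [12.0 + i for i in range(n)],
                "m50_status": ["defined"] * n,
                "musix200": [np.nan] * n,
                "musix200_status": ["no_increase"] * n,
                "cmap50": [15.0 + i for i in range(n)],
                "cmap50_status": ["defined"] * n,
            }
        )
        survival = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "time_months": [40.0 + i for i in range(n)],
                "event": [True] * n,
            }
        )
        return fits, metrics, survival

    def test_single_patient_medians_equal_values(self):
        report = summarize_cohort(*self.tables(1))
        entry = report["strata"]["aggressiveness"]["intermediate"]
        assert entry["m50"]["median"] == 12.0
        assert entry["m50"]["q1"] == entry["m50"]["q3"] == 12.0

    def test_undefined_metric_reports_n_zero(self):
        report = summarize_cohort(*self.tables(4))
        entry = report["strata"]["aggressiveness"]["intermediate"]["musix200"]
        assert entry["n"] == 0 and "median" not in entry

    def test_ordered_subgroups_have_ordered_medians(self):
        fits, metrics, survival = self.tables(6)
        fits["subgroup"] = ["high"] * 3 + ["low"] * 3
        fits["d50"] = [10, 11, 12, 50, 51, 52]
        metrics["m50"] = [5.0, 6.0, 7.0, 25.0, 26.0, 27.0]
        report = summarize_cohort(fits, metrics, survival)
        strata = report["strata"]["aggressiveness"]
        assert strata["high"]["m50"]["median"] < strata["low"]["m50"]["median"]

    def test_survival_split_groups_and_separation_present(self):
        fits, metrics, survival = self.tables(8)
        fits["d50"] = np.arange(10.0, 18.0)
        metrics["m50"] = np.array([5, 6, 7, 8, 20, 21, 22, 23], dtype=float)
        report = summarize_cohort(fits, metrics, survival)
        assert set(report["survival"]) >= {"d50", "m50", "cmap50"}
        groups = report["survival"]["d50"]["groups"]
        assert groups["low"]["n"] + groups["high"]["n"] == 8
        assert sum(report["separation"]["counts"].values()) == 8
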