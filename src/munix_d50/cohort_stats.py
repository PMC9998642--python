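"""Cohort-level statistics: stratified summaries, nonparametric tests,
median splits, separation groups, and Kaplan-Meier survival.

Conventions follow common neurology-cohort practice: medians with IQR
(quartiles by linear interpolation between order statistics),
Kruskal-Wallis across the three aggressiveness subgroups with pairwise
post-hoc comparisons Bonferroni-adjusted by the number of pairs,
Spearman rank correlation for associations, and Kaplan-Meier curves
with log-rank tests for median-split survival comparisons. Patients
with an undefined metric are dropped from that metric's analyses only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "MedianSplit",
    "TestResult",
    "KaplanMeierCurve",
    "median_split",
    "separation_classify",
    "kruskal_wallis_bonferroni",
    "spearman",
    "kaplan_meier",
    "log_rank",
    "summarize_cohort",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    p_adjusted: float | None = None
    group_sizes: tuple[int, ...] = ()
    degenerate: bool = False


@dataclass(frozen=True)
class MedianSplit:
    """Cohort split at the sample median; ties at the cutoff go high
    (the low group is strictly *under* the cutoff)."""

    cutoff: float
    assignment: dict[str, str]
    degenerate: bool = False


@dataclass(frozen=True)
class KaplanMeierCurve:
    """Product-limit survival estimate. ``median`` is the smallest time
    with survival <= 0.5, or NaN if the curve never reaches it."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float
    n: int


def median_split(values: Mapping[str, float]) -> MedianSplit:
    """Split patients at the median of their values (low: value < median,
    high: value >= median). Requires >= 2 defined (non-NaN) values."""
    clean = {k: v for k, v in values.items() if np.isfinite(v)}
    if len(clean) < 2:
        raise ValueError(f"need at least 2 defined values, got {len(clean)}")
    cutoff = float(np.median(list(clean.values())))
    assignment = {k: ("high" if v >= cutoff else "low") for k, v in clean.items()}
    degenerate = len(set(clean.values())) == 1
    return MedianSplit(cutoff=cutoff, assignment=assignment, degenerate=degenerate)


def separation_classify(
    m50_split: MedianSplit, d50_split: MedianSplit
) -> dict[str, str]:
    """Classify each patient by whether M50 and D50 fall on the same side
    of their respective cohort medians."""
    ids = set(m50_split.assignment)
    if ids != set(d50_split.assignment):
        missing = ids.symmetric_difference(d50_split.assignment)
        raise ValueError(f"splits cover different patients: {sorted(missing)}")
    out = {}
    for pid in ids:
        m, d = m50_split.assignment[pid], d50_split.assignment[pid]
        if m == d:
            out[pid] = "same"
        elif m == "low":
            out[pid] = "low_m50_high_d50"
        else:
            out[pid] = "high_m50_low_d50"
    return out


def kruskal_wallis_bonferroni(
    groups: Mapping[str, Sequence[float]],
) -> tuple[TestResult, dict[tuple[str, str], TestResult]]:
    """Kruskal-Wallis H test across groups plus pairwise Mann-Whitney U
    post-hoc tests with Bonferroni adjustment (p_adj = min(1, n_pairs * p)).
    """
    labels = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    sizes = tuple(len(s) for s in samples)
    if all(np.array_equal(s, samples[0]) for s in samples[1:]):
        # identical groups: H = 0 by construction, scipy raises instead
        omnibus = TestResult(0.0, 1.0, group_sizes=sizes)
    else:
        h, p = stats.kruskal(*samples)
        omnibus = TestResult(float(h), float(p), group_sizes=sizes)
    n_pairs = len(labels) * (len(labels) - 1) // 2
    pairwise: dict[tuple[str, str], TestResult] = {}
    for a, b in itertools.combinations(labels, 2):
        xa, xb = np.asarray(groups[a], float), np.asarray(groups[b], float)
        if np.array_equal(xa, xb):
            u, p_raw = float(len(xa) * len(xb) / 2.0), 1.0
        else:
            u, p_raw = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        pairwise[(a, b)] = TestResult(
            float(u),
            float(p_raw),
            p_adjusted=min(1.0, n_pairs * float(p_raw)),
            group_sizes=(len(xa), len(xb)),
        )
    return omnibus, pairwise


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with average ranks for ties; pairs with
    an undefined member are dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"need at least 3 defined pairs, got {len(x)}")
    r, p = stats.spearmanr(x, y)
    return TestResult(float(r), float(p), group_sizes=(len(x),))


def kaplan_meier(times: Sequence[float], events: Sequence[bool]) -> KaplanMeierCurve:
    """Product-limit survival estimator (delegates to lifelines)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise ValueError("empty survival input")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    median = float(kmf.median_survival_time_)
    if not np.isfinite(median):
        median = float("nan")
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(
        kmf.survival_function_.index
    ).to_numpy(dtype=float)
    return KaplanMeierCurve(
        times=grid, survival=surv, at_risk=at_risk, median=median, n=len(times)
    )


def log_rank(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
) -> TestResult:
    """Two-group log-rank test (chi-square, 1 df). Flagged degenerate when
    either group contributes no observed events."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, bool)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, bool)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    degenerate = ea.sum() == 0 or eb.sum() == 0
    if ea.sum() + eb.sum() == 0:
        return TestResult(0.0, 1.0, group_sizes=(len(ta), len(tb)), degenerate=True)
    if np.array_equal(ta, tb) and np.array_equal(ea, eb):
        return TestResult(0.0, 1.0, group_sizes=(len(ta), len(tb)), degenerate=degenerate)
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return TestResult(
        float(res.test_statistic),
        float(res.p_value),
        group_sizes=(len(ta), len(tb)),
        degenerate=bool(degenerate),
    )


# ---------------------------------------------------------------------------
# cohort report


def _median_iqr(values: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {"n": int(len(values)), "median": float(med), "q1": float(q1), "q3": float(q3)}


_METRICS = ("m50", "musix200", "cmap50", "d50", "rd50_at_munix")


def _strata_summary(df: pd.DataFrame, by: str) -> dict:
    out: dict = {}
    for stratum, sub in df.groupby(by):
        if not stratum:
            continue
        entry = {}
        for metric in _METRICS:
            vals = sub[metric].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            entry[metric] = _median_iqr(vals) if len(vals) else {"n": 0}
        out[str(stratum)] = entry
    return out


def summarize_cohort(
    fits: pd.DataFrame,
    metrics: pd.DataFrame,
    survival: pd.DataFrame,
) -> dict:
    """Assemble the cohort report.

    Parameters
    ----------
    fits : d50_fits table (patient_id, d50, dx, subgroup, rd50_at_munix,
        converged, identifiable).
    metrics : patient_metrics table (m50/musix200/cmap50 + statuses).
    survival : patient_id, time_months, event.

    Returns a nested dict: stratified median/IQR summaries per
    aggressiveness subgroup and rD50 phase, Kruskal-Wallis + post-hoc
    results per metric across subgroups, Spearman correlations of each
    metric with D50, median-split Kaplan-Meier survival with log-rank
    tests, and the M50-vs-D50 separation-group census.
    """
    from .d50_model import classify_phase

    usable = fits[fits["converged"] & fits["identifiable"]]
    df = usable.merge(metrics, on="patient_id").merge(survival, on="patient_id")
    df = df.copy()
    df["rd50_phase"] = [
        classify_phase(r) if np.isfinite(r) else "" for r in df["rd50_at_munix"]
    ]

    report: dict = {
        "n_patients": int(len(df)),
        "strata": {
            "aggressiveness": _strata_summary(df, "subgroup"),
            "rd50_phase": _strata_summary(df, "rd50_phase"),
        },
        "overall": {
            m: _median_iqr(v[np.isfinite(v)])
            for m in _METRICS
            if len(v := df[m].to_numpy(dtype=float)) and np.isfinite(v).any()
        },
        "tests": {},
        "survival": {},
        "separation": {},
    }

    # subgroup comparisons and correlations with D50
    for metric in ("m50", "musix200", "cmap50"):
        groups = {
            g: sub[metric].dropna().to_numpy(dtype=float)
            for g, sub in df.groupby("subgroup")
        }
        groups = {g: v for g, v in groups.items() if len(v)}
        entry: dict = {}
        if len(groups) >= 2 and all(len(v) for v in groups.values()):
            if len(groups) >= 3:
                omnibus, pairwise = kruskal_wallis_bonferroni(groups)
                entry["kruskal_wallis"] = {
                    "H": omnibus.statistic,
                    "p": omnibus.p,
                    "group_sizes": omnibus.group_sizes,
                }
                entry["pairwise"] = {
                    f"{a}_vs_{b}": {"p": t.p, "p_bonferroni": t.p_adjusted}
                    for (a, b), t in pairwise.items()
                }
        paired = df[["d50", metric]].dropna()
        if len(paired) >= 3:
            sp = spearman(paired["d50"], paired[metric])
            entry["spearman_vs_d50"] = {"r": sp.statistic, "p": sp.p}
        report["tests"][metric] = entry

    # median-split survival
    splits: dict[str, MedianSplit] = {}
    survival_rows = []
    for metric in ("d50", "m50", "musix200", "cmap50"):
        values = dict(zip(df["patient_id"], df[metric].astype(float)))
        defined = {k: v for k, v in values.items() if np.isfinite(v)}
        if len(defined) < 2:
            continue
        split = median_split(defined)
        splits[metric] = split
        sub = df[df["patient_id"].isin(defined)]
        entry = {"cutoff": split.cutoff, "groups": {}}
        arms = {}
        for side in ("low", "high"):
            ids = [k for k, v in split.assignment.items() if v == side]
            arm = sub[sub["patient_id"].isin(ids)]
            if len(arm) == 0:
                continue
            km = kaplan_meier(arm["time_months"], arm["event"])
            arms[side] = arm
            entry["groups"][side] = {"n": km.n, "median_survival": km.median}
            survival_rows.append(
                {
                    "split": metric,
                    "group": side,
                    "n": km.n,
                    "median_survival": km.median,
                }
            )
        if len(arms) == 2:
            lr = log_rank(
                arms["low"]["time_months"],
                arms["low"]["event"],
                arms["high"]["time_months"],
                arms["high"]["event"],
            )
            entry["log_rank"] = {
                "statistic": lr.statistic,
                "p": lr.p,
                "degenerate": lr.degenerate,
            }
        report["survival"][metric] = entry

    # separation groups (M50 vs D50 median sides)
    if "m50" in splits and "d50" in splits:
        common = set(splits["m50"].assignment) & set(splits["d50"].assignment)
        m50_split = MedianSplit(
            splits["m50"].cutoff,
            {k: v for k, v in splits["m50"].assignment.items() if k in common},
        )
        d50_split = MedianSplit(
            splits["d50"].cutoff,
            {k: v for k, v in splits["d50"].assignment.items() if k in common},
        )
        labels = separation_classify(m50_split, d50_split)
        counts = pd.Series(list(labels.values())).value_counts().to_dict()
        report["separation"] = {
            "counts": {k: int(v) for k, v in counts.items()},
            "assignment": labels,
        }

    report["_survival_table"] = survival_rows
    return report
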