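"""MUNIX-derived biomarkers: floors, sums, control baseline, and the
time-to-threshold parameters M50, MUSIX200 and CMAP50.

The three-muscle (APB + ADM + TA) MUNIX sum of a patient is expressed
as a fraction of the mean control sum, which defines the 100% level at
symptom onset. Assuming an approximately linear decline of MUNIX over
the observed disease phase, the single cross-sectional measurement
``(t_obs, ratio)`` pins down a line through ``(0, 1.0)``, and

    M50 = t_obs * (1 - 0.5) / (1 - ratio)

is the time in months from symptom onset at which the MUNIX sum reaches
50% of the control mean. CMAP50 is the same construction on the CMAP
sum; MUSIX200 is the rising analogue — the time until the MUSIX sum
doubles (200%) relative to the control baseline. A metric is undefined
when the observation is on the wrong side of the baseline (no decrease
for M50/CMAP50, no increase for MUSIX200); this is a status, not an
error, so cohort tables can report per-metric n.

Measurements that could not be obtained (CMAP at or below the 0.5 mV
guideline bound) are replaced by small fixed floor values — MUNIX 2,
CMAP 0.5 mV, MUSIX 250 — so that patients with advanced disease stay in
the cohort instead of biasing it toward mild cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .cohort_io import (
    FLOOR_CMAP_MV,
    FLOOR_MUNIX,
    FLOOR_MUSIX,
    MUSCLES,
    MuscleMeasurement,
    MunixPanel,
)

__all__ = [
    "ControlBaseline",
    "MetricResult",
    "PatientMetrics",
    "apply_floors",
    "compute_musix",
    "sum_scores",
    "control_baseline",
    "time_to_fraction_linear",
    "compute_m50",
    "compute_cmap50",
    "compute_musix200",
    "compute_patient_metrics",
    "metrics_table",
]

MetricStatus = Literal["defined", "no_decrease", "no_increase"]


def compute_musix(cmap_mV: float, munix: float) -> float:
    """MUSIX = CMAP (in microvolts) / MUNIX; the floor pair
    (0.5 mV, 2) gives 500/2 = 250."""
    if munix <= 0:
        raise ValueError(f"munix must be positive, got {munix}")
    return cmap_mV * 1000.0 / munix


def apply_floors(
    muscle: str, munix: float, cmap_mV: float, obtainable: bool = True
) -> MuscleMeasurement:
    """Return the validated measurement, substituting the floor values
    when the signal was unobtainable or CMAP is at or below 0.5 mV."""
    if munix < 0 or cmap_mV < 0:
        raise ValueError("raw munix and cmap must be non-negative")
    if not obtainable or cmap_mV <= FLOOR_CMAP_MV or munix <= 0:
        return MuscleMeasurement(
            muscle=muscle,
            munix=FLOOR_MUNIX,
            cmap_mV=FLOOR_CMAP_MV,
            musix=FLOOR_MUSIX,
            floored=True,
        )
    return MuscleMeasurement(
        muscle=muscle,
        munix=munix,
        cmap_mV=cmap_mV,
        musix=compute_musix(cmap_mV, munix),
        floored=False,
    )


def sum_scores(panel: MunixPanel) -> tuple[float, float, float]:
    """Three-muscle (MUNIX, CMAP mV, MUSIX) sums, floored values included."""
    munix = sum(panel.measurement(m).munix for m in MUSCLES)
    cmap = sum(panel.measurement(m).cmap_mV for m in MUSCLES)
    musix = sum(panel.measurement(m).musix for m in MUSCLES)
    return munix, cmap, musix


@dataclass(frozen=True)
class ControlBaseline:
    """Healthy-control reference defining the 100% level.

    ``per_muscle`` maps muscle -> {"munix_mean", "munix_sd", "cmap_mean",
    "cmap_sd", "musix_mean", "musix_sd"}. Summed means are the sums of
    per-muscle means for MUNIX and CMAP; the MUSIX baseline is the mean
    over controls of per-control MUSIX sums (identical when every
    control has all three muscles, as required).
    """

    per_muscle: dict[str, dict[str, float]]
    munix_sum_mean: float
    cmap_sum_mean_mV: float
    musix_sum_mean: float
    n_controls: int


def control_baseline(controls: pd.DataFrame) -> ControlBaseline:
    """Compute the control baseline from a long-format control table.

    ``controls`` needs columns control_id, muscle, munix, cmap_mV; every
    control must contribute all three muscles exactly once. SDs use the
    n-1 denominator (0 for a single control).
    """
    required = {"control_id", "muscle", "munix", "cmap_mV"}
    missing = required - set(controls.columns)
    if missing:
        raise ValueError(f"control table missing column(s) {sorted(missing)}")
    if len(controls) == 0:
        raise ValueError("control table is empty")
    counts = controls.groupby("control_id")["muscle"].apply(
        lambda m: sorted(m) == sorted(MUSCLES)
    )
    if not counts.all():
        bad = counts[~counts].index.tolist()
        raise ValueError(f"controls missing muscles: {bad}")

    df = controls.copy()
    if (df["munix"] <= 0).any():
        raise ValueError("control MUNIX values must be positive")
    df["musix"] = df["cmap_mV"] * 1000.0 / df["munix"]

    per_muscle: dict[str, dict[str, float]] = {}
    for muscle in MUSCLES:
        sub = df[df["muscle"] == muscle]
        per_muscle[muscle] = {
            "munix_mean": float(sub["munix"].mean()),
            "munix_sd": float(sub["munix"].std(ddof=1)) if len(sub) > 1 else 0.0,
            "cmap_mean": float(sub["cmap_mV"].mean()),
            "cmap_sd": float(sub["cmap_mV"].std(ddof=1)) if len(sub) > 1 else 0.0,
            "musix_mean": float(sub["musix"].mean()),
            "musix_sd": float(sub["musix"].std(ddof=1)) if len(sub) > 1 else 0.0,
        }
    musix_sums = df.groupby("control_id")["musix"].sum()
    return ControlBaseline(
        per_muscle=per_muscle,
        munix_sum_mean=float(sum(per_muscle[m]["munix_mean"] for m in MUSCLES)),
        cmap_sum_mean_mV=float(sum(per_muscle[m]["cmap_mean"] for m in MUSCLES)),
        musix_sum_mean=float(musix_sums.mean()),
        n_controls=int(df["control_id"].nunique()),
    )


def time_to_fraction_linear(
    t_obs_months: float, observed_ratio: float, target_ratio: float
) -> float:
    """Months from onset until a linear trajectory anchored at ratio 1.0
    at t = 0 and passing through ``(t_obs, observed_ratio)`` reaches
    ``target_ratio``.

    Closed form: ``t_obs * (1 - target) / (1 - observed)``. The target
    must lie on the same side of 1.0 as the observation (a falling line
    never doubles; a rising line never halves).
    """
    if t_obs_months <= 0:
        raise ValueError(f"t_obs_months must be positive, got {t_obs_months}")
    if observed_ratio == 1.0:
        raise ValueError("observed ratio equals baseline; trajectory is flat")
    if (target_ratio - 1.0) * (observed_ratio - 1.0) <= 0:
        raise ValueError(
            f"target ratio {target_ratio} unreachable from observed "
            f"{observed_ratio} on a line anchored at 1.0"
        )
    return t_obs_months * (1.0 - target_ratio) / (1.0 - observed_ratio)


@dataclass(frozen=True)
class MetricResult:
    """One time-to-threshold metric: months (NaN when undefined), its
    status, and the observed-to-baseline ratio it came from."""

    months: float
    status: MetricStatus
    ratio: float


def compute_m50(munix_sum: float, t_obs_months: float, baseline: ControlBaseline) -> MetricResult:
    """Months until the MUNIX sum falls to 50% of the control mean sum;
    ``no_decrease`` when the patient sits at or above the baseline."""
    ratio = munix_sum / baseline.munix_sum_mean
    if ratio >= 1.0:
        return MetricResult(float("nan"), "no_decrease", ratio)
    return MetricResult(
        time_to_fraction_linear(t_obs_months, ratio, 0.5), "defined", ratio
    )


def compute_cmap50(cmap_sum_mV: float, t_obs_months: float, baseline: ControlBaseline) -> MetricResult:
    """Months until the CMAP sum falls to 50% of the control mean sum."""
    ratio = cmap_sum_mV / baseline.cmap_sum_mean_mV
    if ratio >= 1.0:
        return MetricResult(float("nan"), "no_decrease", ratio)
    return MetricResult(
        time_to_fraction_linear(t_obs_months, ratio, 0.5), "defined", ratio
    )


def compute_musix200(musix_sum: float, t_obs_months: float, baseline: ControlBaseline) -> MetricResult:
    """Months until the MUSIX sum doubles (200% of the control baseline);
    ``no_increase`` when the patient sits at or below the baseline."""
    ratio = musix_sum / baseline.musix_sum_mean
    if ratio <= 1.0:
        return MetricResult(float("nan"), "no_increase", ratio)
    return MetricResult(
        time_to_fraction_linear(t_obs_months, ratio, 2.0), "defined", ratio
    )


@dataclass(frozen=True)
class PatientMetrics:
    patient_id: str
    t_munix_months: float
    m50: MetricResult
    musix200: MetricResult
    cmap50: MetricResult


def compute_patient_metrics(panel: MunixPanel, baseline: ControlBaseline) -> PatientMetrics:
    """All three metrics for one patient's (floored) panel."""
    munix_sum, cmap_sum, musix_sum = sum_scores(panel)
    t = panel.t_munix_months
    return PatientMetrics(
        patient_id=panel.patient_id,
        t_munix_months=t,
        m50=compute_m50(munix_sum, t, baseline),
        musix200=compute_musix200(musix_sum, t, baseline),
        cmap50=compute_cmap50(cmap_sum, t, baseline),
    )


def metrics_table(records: Iterable, baseline: ControlBaseline) -> pd.DataFrame:
    """patient_metrics table: one row per patient with months, statuses
    and observed/baseline ratios for each metric."""
    rows = []
    for record in records:
        pm = compute_patient_metrics(record.panel, baseline)
        rows.append(
            {
                "patient_id": pm.patient_id,
                "t_munix_months": pm.t_munix_months,
                "m50": pm.m50.months,
                "m50_status": pm.m50.status,
                "munix_ratio": pm.m50.ratio,
                "musix200": pm.musix200.months,
                "musix200_status": pm.musix200.status,
                "musix_ratio": pm.musix200.ratio,
                "cmap50": pm.cmap50.months,
                "cmap50_status": pm.cmap50.status,
                "cmap_ratio": pm.cmap50.ratio,
            }
        )
    return pd.DataFrame(rows)
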