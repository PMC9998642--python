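"""Synthetic ALS cohort generator.

No patient-level data accompany the study design this package
implements, so every pipeline stage is exercised on simulated cohorts
whose statistical structure matches the analysis assumptions:

* ALSFRS-R trajectories follow the sigmoid 48/(1+exp((t-D50)/dx)),
  sampled at a jittered ~2.8-month visit cadence, with additive
  Gaussian noise, clamping to [0, 48] and (by default) integer
  rounding, as the instrument reports integers.
* D50 is drawn from a mixture of three aggressiveness subgroups
  (high/intermediate/low) with per-subgroup truncated log-normal
  distributions calibrated to medians 13.8 / 28.0 / 61.5 months;
  truncation at the subgroup boundaries keeps labels consistent by
  construction.
* The three-muscle MUNIX sum declines linearly from the control-mean
  baseline, crossing 50% exactly at the true M50 = ratio * D50
  (default ratio 0.5); CMAP declines linearly as well (slower), so the
  MUSIX quotient rises. Per-muscle values split the sums in proportion
  to the control means. Floors are applied exactly as in ingestion.
* Healthy controls draw per-muscle MUNIX and CMAP from truncated-at-
  zero normal distributions (MUNIX: APB 168.6±58.6, ADM 154.4±40.2,
  TA 137.2±28.9).
* Survival couples to aggressiveness: time = multiplier * D50 *
  exp(log-normal noise), with a configurable censoring fraction.

Randomness uses one master seed with counter-based per-patient
substreams, so changing the cohort size does not reshuffle existing
patients and identical seeds give byte-identical CSV outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import MUSCLES, MunixPanel, PatientRecord, SurvivalRecord, AlsfrsObservation
from .d50_model import FULL_SCALE, sigmoid_value
from .munix_metrics import apply_floors

__all__ = [
    "GeneratorConfig",
    "TruthRecord",
    "CohortTables",
    "generate_controls",
    "generate_patient",
    "generate_cohort",
    "noiseless",
]

#: healthy-control MUNIX means/SDs per muscle
DEFAULT_CONTROL_MUNIX: Mapping[str, tuple[float, float]] = {
    "APB": (168.6, 58.6),
    "ADM": (154.4, 40.2),
    "TA": (137.2, 28.9),
}
#: healthy-control CMAP (mV) means/SDs per muscle (literature-typical values)
DEFAULT_CONTROL_CMAP: Mapping[str, tuple[float, float]] = {
    "APB": (10.5, 2.4),
    "ADM": (10.9, 2.0),
    "TA": (5.9, 1.5),
}

_CONTROL_STREAM = (1 << 20,)  # spawn key reserved for the control table


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort; defaults are the study
    conditions the analysis assumes (see docs/methods.md)."""

    master_seed: int = 0
    n_patients: int = 222
    n_controls: int = 45

    # aggressiveness mixture (high, intermediate, low), weights sum to 1
    subgroup_weights: tuple[float, float, float] = (64 / 222, 92 / 222, 66 / 222)
    d50_medians: tuple[float, float, float] = (13.8, 28.0, 61.5)
    d50_log_sigmas: tuple[float, float, float] = (0.45, 0.20, 0.45)
    d50_bounds: tuple[tuple[float, float], ...] = ((2.0, 20.0), (20.0, 40.0), (40.0, 300.0))
    dx_to_d50: float = 0.25

    # ALSFRS-R visit schedule and noise
    visit_cadence_months: float = 2.8
    cadence_jitter_sd: float = 0.8
    first_visit_range: tuple[float, float] = (2.0, 6.0)
    followup_range_months: tuple[float, float] = (24.0, 48.0)
    min_tracked_score: float = 12.0
    alsfrs_noise_sd: float = 2.0
    integer_scores: bool = True

    # MUNIX/CMAP trajectories
    m50_to_d50: float = 0.5
    cmap50_to_d50: float = 0.6
    munix_noise_sd: float = 0.10  # log-normal sigma on the sum ratio
    cmap_noise_sd: float = 0.10
    ratio_floor_eps: float = 0.02
    p_unobtainable: float = 0.05
    measurement_rd50_mean: float = 0.28
    measurement_rd50_sd: float = 0.12
    measurement_rd50_range: tuple[float, float] = (0.05, 0.45)

    # controls
    control_munix: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_MUNIX)
    )
    control_cmap: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_CMAP)
    )

    # survival
    survival_multiplier: float = 2.2
    survival_noise_sd: float = 0.35
    censoring_fraction: float = 0.25

    def __post_init__(self) -> None:
        if abs(sum(self.subgroup_weights) - 1.0) > 1e-9:
            raise ValueError("subgroup weights must sum to 1")
        if self.visit_cadence_months <= 0:
            raise ValueError("visit cadence must be positive")
        for name in ("alsfrs_noise_sd", "munix_noise_sd", "cmap_noise_sd",
                     "survival_noise_sd", "cadence_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def noiseless(config: GeneratorConfig | None = None, **overrides) -> GeneratorConfig:
    """A copy of ``config`` with every noise source switched off:
    exact sigmoid scores (no rounding), exact linear MUNIX/CMAP decline,
    controls pinned at their means, no unobtainable measurements and no
    censoring. Under this configuration the pipeline must recover the
    generator's true D50 and M50 to numerical precision."""
    cfg = config or GeneratorConfig()
    changes = dict(
        alsfrs_noise_sd=0.0,
        integer_scores=False,
        munix_noise_sd=0.0,
        cmap_noise_sd=0.0,
        p_unobtainable=0.0,
        censoring_fraction=0.0,
        control_munix={m: (mu, 0.0) for m, (mu, _) in cfg.control_munix.items()},
        control_cmap={m: (mu, 0.0) for m, (mu, _) in cfg.control_cmap.items()},
    )
    changes.update(overrides)
    return replace(cfg, **changes)


@dataclass(frozen=True)
class TruthRecord:
    """Generator ground truth for recovery experiments."""

    patient_id: str
    d50: float
    dx: float
    m50: float
    survival_months: float


@dataclass
class CohortTables:
    """The generated cohort as the pipeline's five input tables plus
    the ground-truth table."""

    alsfrs: pd.DataFrame
    panels: pd.DataFrame
    survival: pd.DataFrame
    metadata: pd.DataFrame
    controls: pd.DataFrame
    truth: pd.DataFrame

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("alsfrs", "munix_panels", "survival", "metadata", "controls", "truth"):
            attr = "panels" if name == "munix_panels" else name
            path = out / f"{name}.csv"
            getattr(self, attr).to_csv(path, index=False)
            paths[name] = path
        return paths


def _rng(config: GeneratorConfig, *key: int) -> np.random.Generator:
    seq = np.random.SeedSequence(entropy=config.master_seed, spawn_key=key)
    return np.random.default_rng(seq)


def _truncated_normal(rng, mean, sd, low, high, size=None):
    if sd == 0:
        return np.full(size, float(mean)) if size is not None else float(mean)
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_controls(
    n: int, config: GeneratorConfig | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Long-format healthy-control table (control_id, muscle, munix,
    cmap_mV); per-muscle values from truncated-at-zero normals."""
    config = config or GeneratorConfig()
    if n < 1:
        raise ValueError(f"need at least one control, got {n}")
    if seed is not None:
        config = replace(config, master_seed=seed)
    rng = _rng(config, *_CONTROL_STREAM)
    ids = [f"C{i:05d}" for i in range(n)]
    frames = []
    for muscle in MUSCLES:
        mu_m, sd_m = config.control_munix[muscle]
        mu_c, sd_c = config.control_cmap[muscle]
        frames.append(
            pd.DataFrame(
                {
                    "control_id": ids,
                    "muscle": muscle,
                    "munix": _truncated_normal(rng, mu_m, sd_m, 0.0, np.inf, size=n),
                    "cmap_mV": _truncated_normal(rng, mu_c, sd_c, 0.0, np.inf, size=n),
                }
            )
        )
    return (
        pd.concat(frames, ignore_index=True)
        .sort_values(["control_id", "muscle"], kind="stable")
        .reset_index(drop=True)
    )


def _sample_d50(rng: np.random.Generator, config: GeneratorConfig, subgroup: int) -> float:
    median = config.d50_medians[subgroup]
    sigma = config.d50_log_sigmas[subgroup]
    low, high = config.d50_bounds[subgroup]
    for _ in range(1000):  # rejection into the subgroup interval
        d50 = float(math.exp(rng.normal(math.log(median), sigma)))
        if low <= d50 < high:
            return d50
    return float(np.clip(median, low, high))


def _control_mean_sums(config: GeneratorConfig) -> tuple[float, float]:
    munix = sum(mu for mu, _ in config.control_munix.values())
    cmap = sum(mu for mu, _ in config.control_cmap.values())
    return munix, cmap


def generate_patient(
    true_d50: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
    patient_id: str = "P0",
) -> tuple[PatientRecord, TruthRecord]:
    """Simulate one patient: sigmoid ALSFRS-R trajectory, one MUNIX
    panel on a linear decline from the control baseline, and a
    D50-coupled survival time."""
    if true_d50 <= 0:
        raise ValueError("true D50 must be positive")
    dx = config.dx_to_d50 * true_d50
    true_m50 = config.m50_to_d50 * true_d50
    true_c50 = config.cmap50_to_d50 * true_d50

    # survival (true event time; censoring decided later)
    true_survival = config.survival_multiplier * true_d50 * math.exp(
        rng.normal(0.0, config.survival_noise_sd)
    )

    # MUNIX measurement time, within the linear-decline regime
    rd50_meas = float(
        _truncated_normal(
            rng,
            config.measurement_rd50_mean,
            config.measurement_rd50_sd,
            *config.measurement_rd50_range,
        )
    )
    t_meas = 2.0 * rd50_meas * true_d50
    true_survival = max(true_survival, t_meas + 1.0)

    # ALSFRS-R visit schedule
    t0 = rng.uniform(*config.first_visit_range)
    horizon = min(true_survival, t0 + rng.uniform(*config.followup_range_months))
    times = [t0]
    while True:
        step = max(0.5, rng.normal(config.visit_cadence_months, config.cadence_jitter_sd))
        t_next = times[-1] + step
        if t_next > horizon and len(times) >= 2:
            break
        times.append(t_next)
        if len(times) >= 2 and sigmoid_value(t_next, true_d50, dx) < config.min_tracked_score:
            break
        if len(times) > 60:
            break
    observations = []
    for t in times:
        value = sigmoid_value(t, true_d50, dx)
        if config.alsfrs_noise_sd > 0:
            value += rng.normal(0.0, config.alsfrs_noise_sd)
        value = float(np.clip(value, 0.0, FULL_SCALE))
        score = int(round(value)) if config.integer_scores else value
        observations.append(
            AlsfrsObservation(patient_id=patient_id, t_months=float(t), score=score)  # type: ignore[arg-type]
        )

    # MUNIX panel: linear sum declines anchored at the control means
    munix_base, cmap_base = _control_mean_sums(config)
    munix_ratio = max(config.ratio_floor_eps, 1.0 - 0.5 * t_meas / true_m50)
    cmap_ratio = max(config.ratio_floor_eps, 1.0 - 0.5 * t_meas / true_c50)
    if config.munix_noise_sd > 0:
        munix_ratio *= math.exp(rng.normal(0.0, config.munix_noise_sd))
    if config.cmap_noise_sd > 0:
        cmap_ratio *= math.exp(rng.normal(0.0, config.cmap_noise_sd))

    measurements = []
    for muscle in MUSCLES:
        frac_m = config.control_munix[muscle][0] / munix_base
        frac_c = config.control_cmap[muscle][0] / cmap_base
        obtainable = rng.uniform() >= config.p_unobtainable
        measurements.append(
            apply_floors(
                muscle=muscle,
                munix=munix_ratio * munix_base * frac_m,
                cmap_mV=cmap_ratio * cmap_base * frac_c,
                obtainable=obtainable,
            )
        )
    panel = MunixPanel(
        patient_id=patient_id,
        t_munix_months=float(t_meas),
        side="less_affected",
        measurements=tuple(measurements),
    )

    censored = rng.uniform() < config.censoring_fraction
    if censored:
        observed_time = max(t_meas + 0.5, rng.uniform(0.5, 1.0) * true_survival)
    else:
        observed_time = true_survival
    survival = SurvivalRecord(
        patient_id=patient_id, time_months=float(observed_time), event=not censored
    )

    age = float(np.clip(rng.normal(65.0, 10.0), 40.0, 90.0))
    metadata = {
        "age_at_measurement": round(age, 1),
        "sex": "female" if rng.uniform() < 0.44 else "male",
        "gold_coast": True,
        "juvenile": False,
        "riluzole": bool(rng.uniform() < 0.9),
    }
    record = PatientRecord(
        patient_id=patient_id,
        observations=tuple(observations),
        panel=panel,
        survival=survival,
        metadata=metadata,
    )
    truth = TruthRecord(
        patient_id=patient_id,
        d50=float(true_d50),
        dx=float(dx),
        m50=float(true_m50),
        survival_months=float(true_survival),
    )
    return record, truth


def generate_cohort(config: GeneratorConfig | None = None) -> CohortTables:
    """Simulate a full cohort and its control table.

    Per-patient substreams are derived from the master seed by a
    counter, so patient i is identical in any cohort of size > i under
    the same seed.
    """
    config = config or GeneratorConfig()
    records: list[PatientRecord] = []
    truths: list[TruthRecord] = []
    weights = np.asarray(config.subgroup_weights, dtype=float)
    for i in range(config.n_patients):
        rng = _rng(config, i)
        subgroup = int(rng.choice(3, p=weights))
        d50 = _sample_d50(rng, config, subgroup)
        record, truth = generate_patient(d50, config, rng, patient_id=f"P{i:05d}")
        records.append(record)
        truths.append(truth)

    controls = generate_controls(config.n_controls, config)

    alsfrs = pd.DataFrame(
        [
            {"patient_id": o.patient_id, "t_months": o.t_months, "alsfrs_r_total": o.score}
            for r in records
            for o in r.observations
        ]
    )
    panels = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "t_munix_months": r.panel.t_munix_months,
                "side": r.panel.side,
                "muscle": m.muscle,
                "munix": m.munix,
                "cmap_mV": m.cmap_mV,
                "obtainable": not m.floored,
            }
            for r in records
            for m in r.panel.measurements
        ]
    )
    survival = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "time_months": r.survival.time_months,
                "event": r.survival.event,
            }
            for r in records
        ]
    )
    metadata = pd.DataFrame(
        [{"patient_id": r.patient_id, **r.metadata} for r in records]
    )
    truth = pd.DataFrame(
        [
            {
                "patient_id": t.patient_id,
                "true_d50": t.d50,
                "true_dx": t.dx,
                "true_m50": t.m50,
                "true_survival_months": t.survival_months,
            }
            for t in truths
        ]
    )
    return CohortTables(
        alsfrs=alsfrs,
        panels=panels,
        survival=survival,
        metadata=metadata,
        controls=controls,
        truth=truth,
    )
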