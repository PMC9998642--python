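"""Cohort data model, CSV ingestion/validation and exclusion rules.

The pipeline consumes four patient tables plus a healthy-control table,
all plain CSV (UTF-8, comma-separated, header row, ``.`` decimal):

* ``alsfrs.csv`` — longitudinal ALSFRS-R totals (patient_id, t_months,
  alsfrs_r_total and optional subscores),
* ``munix_panels.csv`` — one three-muscle MUNIX/CMAP panel per patient
  (long format, one row per muscle),
* ``survival.csv`` — time from symptom onset to death or censoring,
* ``metadata.csv`` — optional demographics and inclusion flags.

All times are decimal months with symptom onset at zero. Cohort-level
exclusion rules mirror common ALS study practice (diagnostic criteria,
measurement side, minimum ALSFRS-R follow-up, juvenile onset, absence of
MUNIX decline, implausibly late M50) and are applied in a fixed order
with an auditable ledger: every input patient lands either in the
retained list or under exactly the first rule it violates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MUSCLES",
    "SchemaError",
    "ValidationError",
    "AlsfrsObservation",
    "MuscleMeasurement",
    "MunixPanel",
    "SurvivalRecord",
    "PatientRecord",
    "ExclusionConfig",
    "ExclusionLedger",
    "EXCLUSION_RULES",
    "read_cohort",
    "write_cohort",
    "apply_exclusions",
]

logger = logging.getLogger(__name__)

MUSCLES = ("APB", "ADM", "TA")

#: Floor substitutions for unobtainable measurements: MUNIX 2, CMAP 0.5 mV,
#: MUSIX 250 (= 500 uV / 2).
FLOOR_MUNIX = 2.0
FLOOR_CMAP_MV = 0.5
FLOOR_MUSIX = 250.0


class SchemaError(ValueError):
    """A mandatory column is missing or a table cannot be parsed."""


class ValidationError(ValueError):
    """A row violates a domain invariant (reported with its location)."""


@dataclass(frozen=True)
class AlsfrsObservation:
    """One ALSFRS-R total score at a time since symptom onset.

    Scores are integers on the instrument's 0-48 scale; continuous
    values are accepted so that exact model trajectories round-trip.
    """

    patient_id: str
    t_months: float
    score: float

    def __post_init__(self) -> None:
        if not 0 <= self.score <= 48:
            raise ValidationError(
                f"patient {self.patient_id}: ALSFRS-R score {self.score} "
                "outside 0-48"
            )
        if self.t_months < 0:
            raise ValidationError(
                f"patient {self.patient_id}: negative time {self.t_months}"
            )


@dataclass(frozen=True)
class MuscleMeasurement:
    """Per-muscle MUNIX, CMAP (mV) and MUSIX with the floor flag.

    A floored measurement carries the fixed substitution values
    (MUNIX 2, CMAP 0.5 mV, MUSIX 250); otherwise MUSIX is the quotient
    CMAP(uV)/MUNIX.
    """

    muscle: str
    munix: float
    cmap_mV: float
    musix: float
    floored: bool

    def __post_init__(self) -> None:
        if self.muscle not in MUSCLES:
            raise ValidationError(f"unknown muscle {self.muscle!r}")
        if self.floored:
            if (self.munix, self.cmap_mV, self.musix) != (
                FLOOR_MUNIX,
                FLOOR_CMAP_MV,
                FLOOR_MUSIX,
            ):
                raise ValidationError(
                    f"floored {self.muscle} measurement must carry the floor "
                    f"values ({FLOOR_MUNIX}, {FLOOR_CMAP_MV} mV, {FLOOR_MUSIX})"
                )
        else:
            if self.cmap_mV <= FLOOR_CMAP_MV:
                raise ValidationError(
                    f"{self.muscle}: CMAP {self.cmap_mV} mV at or below the "
                    "0.5 mV guideline bound must be floored"
                )
            if self.munix <= 0:
                raise ValidationError(f"{self.muscle}: non-positive MUNIX")
            expected = self.cmap_mV * 1000.0 / self.munix
            if abs(self.musix - expected) > 1e-9 * max(abs(expected), 1.0):
                raise ValidationError(
                    f"{self.muscle}: MUSIX {self.musix} inconsistent with "
                    f"CMAP/MUNIX quotient {expected}"
                )


@dataclass(frozen=True)
class MunixPanel:
    """Three-muscle MUNIX panel at a single time in the disease course."""

    patient_id: str
    t_munix_months: float
    side: str
    measurements: tuple[MuscleMeasurement, ...]

    def __post_init__(self) -> None:
        if self.t_munix_months <= 0:
            raise ValidationError(
                f"patient {self.patient_id}: non-positive measurement time"
            )
        if self.side not in ("less_affected", "more_affected"):
            raise ValidationError(
                f"patient {self.patient_id}: unknown side {self.side!r}"
            )
        muscles = sorted(m.muscle for m in self.measurements)
        if muscles != sorted(MUSCLES):
            raise ValidationError(
                f"patient {self.patient_id}: panel must contain each of "
                f"{MUSCLES} exactly once, got {muscles}"
            )

    def measurement(self, muscle: str) -> MuscleMeasurement:
        for m in self.measurements:
            if m.muscle == muscle:
                return m
        raise KeyError(muscle)


@dataclass(frozen=True)
class SurvivalRecord:
    """Months from symptom onset to death (event) or censoring."""

    patient_id: str
    time_months: float
    event: bool

    def __post_init__(self) -> None:
        if self.time_months <= 0:
            raise ValidationError(
                f"patient {self.patient_id}: non-positive survival time"
            )


@dataclass(frozen=True)
class PatientRecord:
    """All inputs for one patient, keyed by a shared opaque id."""

    patient_id: str
    observations: tuple[AlsfrsObservation, ...]
    panel: MunixPanel
    survival: SurvivalRecord
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [o.t_months for o in self.observations]
        if times != sorted(times):
            raise ValidationError(
                f"patient {self.patient_id}: observations not sorted by time"
            )
        for component in (self.panel, self.survival, *self.observations):
            if component.patient_id != self.patient_id:
                raise ValidationError(
                    f"patient {self.patient_id}: component carries id "
                    f"{component.patient_id!r}"
                )


# ---------------------------------------------------------------------------
# reading


def _require_columns(df: pd.DataFrame, required: Sequence[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing mandatory column(s) {missing}")


def _read_csv(path: str | Path, name: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except FileNotFoundError:
        raise SchemaError(f"{name}: file not found: {path}") from None


def read_cohort(
    path_alsfrs: str | Path,
    path_panels: str | Path,
    path_survival: str | Path,
    path_metadata: str | Path | None = None,
) -> list[PatientRecord]:
    """Read and cross-validate the cohort tables into patient records.

    Patients must appear in all three mandatory tables (ALSFRS-R, panel,
    survival); patients missing from any are omitted and logged.
    Floors are applied to each muscle row on ingestion: a measurement
    flagged unobtainable, or with CMAP at or below 0.5 mV, is replaced
    by the fixed floor values.

    Raises
    ------
    SchemaError
        if a mandatory column is absent.
    ValidationError
        if a row violates a domain invariant; the message names the
        offending table row.
    """
    from .munix_metrics import apply_floors  # local import, avoids cycle

    alsfrs = _read_csv(path_alsfrs, "alsfrs")
    panels = _read_csv(path_panels, "munix_panels")
    survival = _read_csv(path_survival, "survival")
    _require_columns(alsfrs, ["patient_id", "t_months", "alsfrs_r_total"], "alsfrs")
    _require_columns(
        panels,
        ["patient_id", "t_munix_months", "side", "muscle", "munix", "cmap_mV", "obtainable"],
        "munix_panels",
    )
    _require_columns(survival, ["patient_id", "time_months", "event"], "survival")

    metadata: dict[str, dict[str, object]] = {}
    if path_metadata is not None:
        meta = _read_csv(path_metadata, "metadata")
        _require_columns(meta, ["patient_id"], "metadata")
        for _, row in meta.iterrows():
            metadata[str(row["patient_id"])] = {
                k: row[k] for k in meta.columns if k != "patient_id"
            }

    observations: dict[str, list[AlsfrsObservation]] = {}
    for i, row in alsfrs.iterrows():
        pid = str(row["patient_id"])
        raw_score = float(row["alsfrs_r_total"])
        try:
            obs = AlsfrsObservation(
                patient_id=pid,
                t_months=float(row["t_months"]),
                # the instrument reports integers, but simulated noiseless
                # trajectories are continuous; preserve either exactly
                score=int(raw_score) if raw_score.is_integer() else raw_score,
            )
        except ValidationError as exc:
            raise ValidationError(f"alsfrs row {i}: {exc}") from None
        observations.setdefault(pid, []).append(obs)

    panel_rows: dict[str, list[pd.Series]] = {}
    for i, row in panels.iterrows():
        pid = str(row["patient_id"])
        seen = {r["muscle"] for r in panel_rows.get(pid, [])}
        if row["muscle"] in seen:
            raise ValidationError(
                f"munix_panels row {i}: duplicate muscle {row['muscle']!r} "
                f"for patient {pid}"
            )
        panel_rows.setdefault(pid, []).append(row)

    panels_by_id: dict[str, MunixPanel] = {}
    for pid, rows in panel_rows.items():
        measurements = tuple(
            apply_floors(
                muscle=str(r["muscle"]),
                munix=float(r["munix"]),
                cmap_mV=float(r["cmap_mV"]),
                obtainable=bool(r["obtainable"]),
            )
            for r in rows
        )
        panels_by_id[pid] = MunixPanel(
            patient_id=pid,
            t_munix_months=float(rows[0]["t_munix_months"]),
            side=str(rows[0]["side"]),
            measurements=measurements,
        )

    survival_by_id: dict[str, SurvivalRecord] = {}
    for i, row in survival.iterrows():
        pid = str(row["patient_id"])
        if pid in survival_by_id:
            raise ValidationError(f"survival row {i}: duplicate patient {pid}")
        survival_by_id[pid] = SurvivalRecord(
            patient_id=pid,
            time_months=float(row["time_months"]),
            event=bool(row["event"]),
        )

    records: list[PatientRecord] = []
    all_ids = sorted(set(observations) | set(panels_by_id) | set(survival_by_id))
    for pid in all_ids:
        missing = [
            name
            for name, table in (
                ("alsfrs", observations),
                ("munix_panels", panels_by_id),
                ("survival", survival_by_id),
            )
            if pid not in table
        ]
        if missing:
            logger.warning("patient %s missing from table(s) %s; omitted", pid, missing)
            continue
        records.append(
            PatientRecord(
                patient_id=pid,
                observations=tuple(
                    sorted(observations[pid], key=lambda o: o.t_months)
                ),
                panel=panels_by_id[pid],
                survival=survival_by_id[pid],
                metadata=metadata.get(pid, {}),
            )
        )
    return records


def write_cohort(records: Iterable[PatientRecord], out_dir: str | Path) -> dict[str, Path]:
    """Write records back to the four-table CSV layout (round-trippable)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = list(records)

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
    meta_rows = []
    for r in records:
        if r.metadata:
            meta_rows.append({"patient_id": r.patient_id, **r.metadata})
    paths = {
        "alsfrs": out / "alsfrs.csv",
        "munix_panels": out / "munix_panels.csv",
        "survival": out / "survival.csv",
    }
    alsfrs.to_csv(paths["alsfrs"], index=False)
    panels.to_csv(paths["munix_panels"], index=False)
    survival.to_csv(paths["survival"], index=False)
    if meta_rows:
        paths["metadata"] = out / "metadata.csv"
        pd.DataFrame(meta_rows).to_csv(paths["metadata"], index=False)
    return paths


# ---------------------------------------------------------------------------
# exclusions

#: Rule ids in application order; the first matching rule claims the patient.
EXCLUSION_RULES = (
    "gold_coast_not_met",
    "more_affected_side",
    "insufficient_alsfrs",
    "juvenile_onset",
    "no_munix_decrease",
    "exceeds_life_expectancy",
)


@dataclass(frozen=True)
class ExclusionConfig:
    """Cutoffs for the life-expectancy exclusion rule.

    M50 is implausible when onset age plus M50 would exceed
    ``life_expectancy_years``; when onset age is unknown the absolute
    cap ``m50_cap_months`` applies instead.
    """

    life_expectancy_years: float = 100.0
    m50_cap_months: float = 720.0


@dataclass
class ExclusionLedger:
    """Counts and patient ids per exclusion rule, plus the retained ids."""

    counts: dict[str, int] = field(
        default_factory=lambda: {rule: 0 for rule in EXCLUSION_RULES}
    )
    excluded: dict[str, list[str]] = field(
        default_factory=lambda: {rule: [] for rule in EXCLUSION_RULES}
    )
    retained: list[str] = field(default_factory=list)

    def record(self, rule: str, patient_id: str) -> None:
        self.counts[rule] += 1
        self.excluded[rule].append(patient_id)

    @property
    def n_excluded(self) -> int:
        return sum(self.counts.values())

    def as_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "excluded": {k: list(v) for k, v in self.excluded.items()},
            "retained": list(self.retained),
        }


def _first_violated_rule(record: PatientRecord, baseline, config: ExclusionConfig):
    from .munix_metrics import compute_m50, sum_scores

    meta = record.metadata or {}
    gold_coast = meta.get("gold_coast", True)
    if not (pd.isna(gold_coast) or bool(gold_coast)):
        return "gold_coast_not_met"
    if record.panel.side == "more_affected":
        return "more_affected_side"
    if len(record.observations) < 2:
        return "insufficient_alsfrs"
    juvenile = meta.get("juvenile", False)
    if not pd.isna(juvenile) and bool(juvenile):
        return "juvenile_onset"
    munix_sum, _, _ = sum_scores(record.panel)
    m50 = compute_m50(munix_sum, record.panel.t_munix_months, baseline)
    if m50.status == "no_decrease":
        return "no_munix_decrease"
    age = meta.get("age_at_measurement")
    if age is not None and not pd.isna(age):
        # onset age = age at measurement minus disease duration at measurement
        onset_age = float(age) - record.panel.t_munix_months / 12.0
        if onset_age + m50.months / 12.0 > config.life_expectancy_years:
            return "exceeds_life_expectancy"
    elif m50.months > config.m50_cap_months:
        return "exceeds_life_expectancy"
    return None


def apply_exclusions(
    records: Sequence[PatientRecord],
    baseline,
    config: ExclusionConfig | None = None,
) -> tuple[list[PatientRecord], ExclusionLedger]:
    """Apply the exclusion rules in order; first matching rule wins.

    Parameters
    ----------
    records : patient records from :func:`read_cohort`.
    baseline : :class:`~munix_d50.munix_metrics.ControlBaseline`
        healthy-control reference needed by the MUNIX-decrease and
        life-expectancy rules.
    config : optional :class:`ExclusionConfig`.

    Returns the retained records and a conservation-checked ledger
    (every input id appears exactly once across retained and rules).
    """
    config = config or ExclusionConfig()
    ledger = ExclusionLedger()
    retained: list[PatientRecord] = []
    for record in records:
        rule = _first_violated_rule(record, baseline, config)
        if rule is None:
            retained.append(record)
            ledger.retained.append(record.patient_id)
        else:
            ledger.record(rule, record.patient_id)
    assert len(retained) + ledger.n_excluded == len(records)
    return retained, ledger
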