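"""End-to-end study pipeline: ingest (or simulate) -> exclusions ->
D50 fits -> MUNIX metrics -> cohort statistics, with reproducible
artifacts on disk.

Every stage is a pure function of its inputs and the configuration, so
re-running with the same seed and config yields byte-identical output
files (the run manifest records the config hash to make this checkable).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort_io import ExclusionConfig, apply_exclusions, read_cohort
from .cohort_stats import summarize_cohort
from .d50_model import fit_cohort
from .munix_metrics import control_baseline, metrics_table
from .synthetic import CohortTables, GeneratorConfig, generate_cohort

__all__ = ["InputPaths", "RunConfig", "RunResult", "run_study"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InputPaths:
    alsfrs: Path
    panels: Path
    survival: Path
    controls: Path
    metadata: Path | None = None


@dataclass(frozen=True)
class RunConfig:
    """Exactly one of ``inputs`` (paths to existing CSVs) or
    ``generator`` (synthetic-cohort parameters) must be given."""

    out_dir: Path
    inputs: InputPaths | None = None
    generator: GeneratorConfig | None = None
    exclusion: ExclusionConfig = field(default_factory=ExclusionConfig)

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.generator is None):
            raise ValueError(
                "exactly one of input paths or a generator config is required"
            )


@dataclass
class RunResult:
    report: dict
    fits: pd.DataFrame
    metrics: pd.DataFrame
    ledger: "object"
    artifacts: dict[str, Path]


def _config_hash(config: RunConfig) -> str:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, dict):
            return {k: encode(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        return obj

    payload = json.dumps(encode(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_study(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write all artifacts to
    ``config.out_dir``: d50_fits.csv, patient_metrics.csv,
    exclusion_ledger.json, cohort_report.json, survival_summary.csv and
    manifest.json (plus inputs/ when simulating)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    if config.generator is not None:
        tables: CohortTables = generate_cohort(config.generator)
        input_dir = out / "inputs"
        paths = tables.write(input_dir)
        artifacts.update({f"input_{k}": v for k, v in paths.items()})
        records = read_cohort(
            paths["alsfrs"], paths["munix_panels"], paths["survival"], paths["metadata"]
        )
        controls = pd.read_csv(paths["controls"])
    else:
        inp = config.inputs
        assert inp is not None
        records = read_cohort(inp.alsfrs, inp.panels, inp.survival, inp.metadata)
        controls = pd.read_csv(inp.controls)

    baseline = control_baseline(controls)
    logger.info("read %d patients, %d controls", len(records), baseline.n_controls)

    retained, ledger = apply_exclusions(records, baseline, config.exclusion)
    logger.info("retained %d patients (%d excluded)", len(retained), ledger.n_excluded)

    fits = fit_cohort(retained)
    metrics = metrics_table(retained, baseline)
    survival = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "time_months": r.survival.time_months,
                "event": r.survival.event,
            }
            for r in retained
        ]
    )
    report = summarize_cohort(fits, metrics, survival)
    survival_table = pd.DataFrame(
        report.pop("_survival_table"),
        columns=["split", "group", "n", "median_survival"],
    )

    artifacts["d50_fits"] = out / "d50_fits.csv"
    fits.to_csv(artifacts["d50_fits"], index=False)
    artifacts["patient_metrics"] = out / "patient_metrics.csv"
    metrics.to_csv(artifacts["patient_metrics"], index=False)
    artifacts["exclusion_ledger"] = out / "exclusion_ledger.json"
    artifacts["exclusion_ledger"].write_text(
        json.dumps(ledger.as_dict(), indent=2, sort_keys=True)
    )
    artifacts["cohort_report"] = out / "cohort_report.json"
    artifacts["cohort_report"].write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_json_default)
    )
    artifacts["survival_summary"] = out / "survival_summary.csv"
    survival_table.to_csv(artifacts["survival_summary"], index=False)

    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.generator.master_seed if config.generator else None,
        "n_input": len(records),
        "n_retained": len(retained),
    }
    artifacts["manifest"] = out / "manifest.json"
    artifacts["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return RunResult(
        report=report, fits=fits, metrics=metrics, ledger=ledger, artifacts=artifacts
    )


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray, tuple, set)):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
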