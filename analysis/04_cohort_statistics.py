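#!/usr/bin/env python
"""Cohort-level statistics: biomarker medians stratified by
aggressiveness subgroup and rD50 phase, Kruskal-Wallis comparisons with
Bonferroni-adjusted post-hocs, Spearman correlations with D50,
median-split Kaplan-Meier survival with log-rank tests, and the
M50-vs-D50 separation-group census.

Reads results/{cohort_inputs,d50_fits.csv,patient_metrics.csv}, writes
results/cohort_report.json and results/survival_summary.csv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from munix_d50.cohort_stats import summarize_cohort
from munix_d50.pipeline import _json_default

parser = argparse.ArgumentParser()
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

fits = pd.read_csv(args.results / "d50_fits.csv")
metrics = pd.read_csv(args.results / "patient_metrics.csv")
survival = pd.read_csv(args.results / "cohort_inputs" / "survival.csv")

report = summarize_cohort(fits, metrics, survival)
survival_table = pd.DataFrame(
    report.pop("_survival_table"), columns=["split", "group", "n", "median_survival"]
)
(args.results / "cohort_report.json").write_text(
    json.dumps(report, indent=2, sort_keys=True, default=_json_default)
)
survival_table.to_csv(args.results / "survival_summary.csv", index=False)

print(f"analysed {report['n_patients']} patients")
for sg, entry in report["strata"]["aggressiveness"].items():
    print(f"  {sg}: M50 median {entry['m50'].get('median', float('nan')):.1f} months "
          f"(n={entry['m50']['n']}), D50 median {entry['d50'].get('median', float('nan')):.1f}")
for metric, entry in report["tests"].items():
    if "kruskal_wallis" in entry:
        print(f"  {metric} across subgroups: H={entry['kruskal_wallis']['H']:.1f}, "
              f"p={entry['kruskal_wallis']['p']:.2g}")
d50_surv = report["survival"].get("d50", {})
if "groups" in d50_surv:
    g = d50_surv["groups"]
    print(f"  D50 median split survival: low {g['low']['median_survival']:.0f} vs "
          f"high {g['high']['median_survival']:.0f} months "
          f"(log-rank p={d50_surv['log_rank']['p']:.2g})")
if report["separation"]:
    print("  separation groups:", report["separation"]["counts"])
print(f"wrote {args.results/'cohort_report.json'} and {args.results/'survival_summary.csv'}")
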