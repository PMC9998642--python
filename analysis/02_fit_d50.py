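#!/usr/bin/env python
"""Fit the sigmoid D50 disease-progression model to every patient's
ALSFRS-R trajectory and classify aggressiveness subgroups.

Reads results/cohort_inputs/, writes results/d50_fits.csv.
"""

import argparse
from pathlib import Path

from munix_d50.cohort_io import read_cohort
from munix_d50.d50_model import fit_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--inputs", type=Path, default=Path("results/cohort_inputs"))
parser.add_argument("--out", type=Path, default=Path("results/d50_fits.csv"))
args = parser.parse_args()

records = read_cohort(
    args.inputs / "alsfrs.csv",
    args.inputs / "munix_panels.csv",
    args.inputs / "survival.csv",
    args.inputs / "metadata.csv",
)
fits = fit_cohort(records)
args.out.parent.mkdir(parents=True, exist_ok=True)
fits.to_csv(args.out, index=False)

usable = fits[fits.converged & fits.identifiable]
print(f"fitted {len(fits)} patients ({len(usable)} converged & identifiable)")
print(f"  D50 median {usable.d50.median():.1f} months "
      f"(IQR {usable.d50.quantile(0.25):.1f}-{usable.d50.quantile(0.75):.1f})")
print("  aggressiveness subgroups:", usable.subgroup.value_counts().to_dict())
print(f"wrote {args.out}")
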