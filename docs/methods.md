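# Methods

## The problem

Disease progression in amyotrophic lateral sclerosis (ALS) is
conventionally tracked with the revised ALS Functional Rating Scale
(ALSFRS-R, 12 items, total 0–48). Electrophysiological indices — the
motor unit number index (MUNIX), the compound muscle action potential
(CMAP) and the motor unit size index (MUSIX = CMAP in µV / MUNIX) —
measure lower-motor-neuron loss directly and are known to decline
before clinical function does. This package implements a pipeline that
puts both on a common time axis: a sigmoidal model of functional
decline per patient, and time-to-threshold biomarkers that convert a
single cross-sectional three-muscle MUNIX panel (APB, ADM, TA) into
months-from-onset quantities comparable with the functional model's
parameters.

## The D50 model

Each patient's ALSFRS-R trajectory is modelled as a logistic decay

    ALSFRS-R(t) = 48 / (1 + exp((t − D50) / dx)),

with t in months since symptom onset. D50 is the turning point — the
time at which half of full motor function is lost (ALSFRS-R = 24) — and
measures disease *aggressiveness* (smaller = more aggressive). dx sets
the steepness of the decline; it is a nuisance parameter here. The
functional form is the unique standard logistic consistent with a
48-point full scale and a turning point at half scale.

Relative D50, rD50 = t / (2·D50), is the *accumulation* coordinate: 0
at onset, 0.5 at the 50%-loss point, comparable across patients of any
aggressiveness. Patients stratify into aggressiveness subgroups by D50
(high [0, 20), intermediate [20, 40), low [40, ∞) months) and rD50
phases (I [0, 0.25), II [0.25, 0.5), III/IV [0.5, ∞)); all intervals
are half-open at the top.

### Fitting

Bounded nonlinear least squares (`scipy.optimize.least_squares`),
D50 ∈ [0.1, 600], dx ∈ [0.1, 120] months. D50 is initialised at the
first piecewise-linear crossing of 24 in the raw observations (falling
back to the last observation time), dx at a quarter of the observation
span; up to five multi-starts jitter the D50 start by ±50% before
non-convergence is declared. Tolerances are set tight (1e-14) so that
noiseless trajectories refit to machine precision. Trajectories with
no strictly decreasing pair of scores carry `identifiable = False`;
the fit is still reported but the patient is dropped from downstream
statistics. At least two observations are required (also an exclusion
rule at cohort level).

## M50, MUSIX200, CMAP50

The healthy-control table defines a 100% baseline: per-muscle means
and SDs of MUNIX, CMAP and MUSIX, and three-muscle sums of means. The
MUSIX baseline is the mean over controls of per-control MUSIX sums;
because every control must contribute all three muscles, this equals
the sum of per-muscle MUSIX means exactly, so no separate aggregation
convention is needed.

A patient's panel gives sums (MUNIX, CMAP, MUSIX) at one time t_obs;
each sum over the control-mean sum is a ratio. Assuming a linear
trajectory of the ratio anchored at 1.0 at symptom onset (the
baseline is defined as 100% at t = 0) and passing through
(t_obs, ratio), the time to any target fraction is

    t_target = t_obs · (1 − target) / (1 − ratio).

M50 and CMAP50 use target 0.5 on the falling MUNIX and CMAP ratios;
MUSIX200 uses target 2.0 on the rising MUSIX ratio. A metric is
*undefined* — a status, not an error — when the observation is on the
wrong side of the baseline (ratio ≥ 1 for M50/CMAP50: "no decrease";
ratio ≤ 1 for MUSIX200: "no increase"), so cohort tables report a
reduced n for that metric, and the no-decrease case feeds the
exclusion rule for M50.

Anchoring at exactly 1.0 at t = 0 is a modelling convention: motor
units are already lost at symptom onset in ALS, so the true
pre-symptomatic trajectory is unknown; the linear estimate should be
read as "months to threshold under a linear decline from an assumed
intact baseline at onset".

### Floors

When a muscle's signal is unobtainable, or CMAP does not exceed the
0.5 mV guideline bound, the measurement is replaced by fixed floor
values — MUNIX 2, CMAP 0.5 mV, MUSIX 250 (= 500 µV / 2) — rather than
dropped. This keeps patients with advanced disease in the cohort;
dropping them would bias the remaining cohort toward mild disease.
Floors are applied at ingestion, before any ratio is computed.

## Exclusion rules

Applied in a fixed order, first match wins, with a conservation-checked
ledger (every input patient is retained or claimed by exactly one
rule): (1) diagnostic (Gold Coast) criteria not met; (2) panel measured
on the clinically more affected side; (3) fewer than two ALSFRS-R
observations; (4) juvenile onset; (5) no MUNIX decrease relative to
controls (M50 undefined); (6) M50 beyond plausible life expectancy.
Rule 6 has no canonical cutoff; the default flags patients whose onset
age plus M50 would exceed 100 years, or M50 > 720 months when onset age
is unknown. Both cutoffs are configurable (`ExclusionConfig`).

## Cohort statistics

- Median and IQR with quartiles by linear interpolation between order
  statistics (`numpy.percentile` default).
- Kruskal–Wallis H (tie-corrected, chi-square approximation) across
  the three aggressiveness subgroups; post-hoc pairwise Mann–Whitney U
  with Bonferroni adjustment p_adj = min(1, 3·p). Spearman rank
  correlation for metric-vs-D50 association.
- Median splits: cutoff at the cohort median; ties at the cutoff go to
  the high group (the low group is strictly *under* the median).
  Separation groups classify patients by whether M50 and D50 fall on
  the same side of their respective medians.
- Kaplan–Meier curves and two-group log-rank tests via `lifelines`;
  the KM median is the smallest time with survival ≤ 0.5. Survival
  times are measured from symptom onset, like every other time in the
  pipeline. A log-rank comparison where either arm has no observed
  events is flagged degenerate.
- Patients with an undefined metric are dropped from that metric's
  analyses only.

## Synthetic cohorts

The generator (`munix_d50.synthetic`) produces the five input tables
plus a ground-truth table, and is the basis of all validation:

- **D50 mixture.** Subgroup weights (64, 92, 66)/222; per-subgroup
  log-normal D50 with medians 13.8 / 28.0 / 61.5 months (log-SDs 0.45 /
  0.20 / 0.45), rejection-truncated to [2, 20), [20, 40), [40, 300) so
  labels hold by construction. dx = 0.25·D50.
- **Visits.** First visit uniform in 2–6 months after onset, then
  steps of mean 2.8 months (SD 0.8, floor 0.5); follow-up ends at the
  earlier of death and a 24–48-month horizon, or once the model score
  falls below 12 (assessments stop in advanced disease). At least two
  visits are always emitted. Scores get additive N(0, 2²) noise,
  clamping to [0, 48] and integer rounding (`integer_scores=True`).
- **Panels.** Measurement time is set by an rD50 value from a
  truncated normal (mean 0.28, SD 0.12, clipped to [0.05, 0.45] — the
  clip keeps every simulated patient inside the linear-decline regime
  so that noiseless recovery is exact). The MUNIX sum ratio declines
  linearly, crossing 0.5 exactly at the true M50 = 0.5·D50; the CMAP
  sum ratio likewise with CMAP50 = 0.6·D50. Multiplicative log-normal
  noise (σ = 0.10) on each ratio; per-muscle values split the sums in
  proportion to the control means; each muscle is unobtainable with
  probability 0.05, after which the ingestion floor rules apply.
  MUSIX is *derived* (CMAP/MUNIX), so its rising trajectory and the
  resulting MUSIX200 are emergent rather than dialled.
- **Controls.** Truncated-at-zero normals per muscle: MUNIX APB
  168.6 ± 58.6, ADM 154.4 ± 40.2, TA 137.2 ± 28.9; CMAP (mV) APB
  10.5 ± 2.4, ADM 10.9 ± 2.0, TA 5.9 ± 1.5 (typical healthy-adult
  amplitudes). 45 controls by default.
- **Survival.** time = 2.2 · D50 · exp(N(0, 0.35²)), never earlier
  than the panel measurement; 25% of patients are censored at a
  uniform fraction of their event time.
- **Seeding.** One master seed; per-patient substreams via
  `numpy.random.SeedSequence(entropy=seed, spawn_key=(i,))`, so patient
  i is unchanged when the cohort grows and identical seeds give
  byte-identical CSVs.

`noiseless(config)` switches off every noise source (including integer
rounding and control SDs); under it the pipeline recovers each
patient's true D50 to ~1e-15 and true M50 to ~1e-16 relative error, a
joint consistency check of the generator, the ingestion path, the
optimiser and the closed-form metric.

### What the generator does and does not emulate

It reproduces the analysis assumptions (sigmoid functional decline,
linear sum-ratio declines, floors, aggressiveness-coupled survival)
and the published marginal quantities (control means, visit cadence,
subgroup medians, rD50 distribution at measurement). It does **not**
emulate: per-muscle heterogeneity beyond a proportional split,
non-linear or pre-symptomatic MUNIX kinetics, bulbar-phenotype effects
on ALSFRS-R subscores, or real dropout processes — the simulated
follow-up is somewhat denser than a routine clinic's (median
observations per patient ≈ 6/11/12 across the high/intermediate/low
subgroups versus 3/7/11 in a comparable clinical cohort). Because the
generated MUSIX rise is emergent and convex, its *linear* MUSIX200
estimate overshoots (cohort medians ≈ 60 months rather than the
~17 months a real cohort shows), and roughly a quarter of simulated
patients have no MUSIX increase at measurement. Passing tests
therefore demonstrate correctness of the estimation machinery under
the stated model, not fidelity of MUSIX200 dynamics to real
reinnervation.

## Numerical choices and degenerate inputs

- Half-open interval classifiers exactly as defined above; boundary
  values (rD50 = 0.25, D50 = 20) go to the upper class.
- `time_to_fraction_linear` rejects ratio = 1 (flat line) and targets
  on the wrong side of 1 as errors; the metric wrappers convert these
  into statuses instead.
- Exact-tie median splits send the tied patient high; an all-equal
  cohort is flagged degenerate (all high).
- Kruskal–Wallis on identical groups returns H = 0, p = 1 directly
  (scipy rejects the all-tied case).
- Control SD with a single control is reported as 0.
- Fit diagnostics (`converged`, `identifiable`) are never silently
  dropped; `fit_cohort` leaves unusable fits in the table with an
  empty subgroup label.

## Problem sizes

Validation experiments use cohorts of 100–222 patients (the full
pipeline fits ~2,200 trajectories across ten seeds in well under a
minute), 20,000–100,000 simulated controls for calibration checks, and
1,000 random triples for the linear-estimation oracle comparison.
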