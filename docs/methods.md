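# Methods

This note documents the models, conventions and design choices behind
`akih`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Detection and staging model

AKI is operationalized purely through serum creatinine (SCr). At an
evaluation time *t* two references may exist:

* **initial SCr** — min(SCr_a, SCr_b), where SCr_a is the first
  measurement within ±61 days of the registration date and SCr_b the
  first measurement after registration (unbounded); whichever exists if
  only one does;
* **recent SCr** — the minimum over [t − 21 d, t).

Detection fires when the current SCr exceeds 1.5× a reference
(strict) or exceeds it by more than 0.3 mg/dL (strict). The triggering
reference becomes the staging baseline; when both trigger, the smaller
is used. This tie rule maximizes the computed ratio, i.e. it is
conservative toward catching severe injury; the alternative (larger
reference) would systematically under-stage.

Staging over [onset, onset + 14 d) uses the window maximum M: stage 3
if M/b ≥ 3.0 or M ≥ 4.0 mg/dL; otherwise the maximum of the
ratio-band stage ([1.5, 2.0) → 1, [2.0, 3.0) → 2) and the increment
stage (1 if M − b > 0.3). Since b > 0, the maximal ratio and maximal
increment over a window are both attained at M, so staging needs only
the window maximum.

Conventions fixed for determinism:

* all windows half-open, the evaluation instant excluded from its own
  history; "two months" = 61 d, "three weeks" = 21 d, "two weeks" = 14 d
  (no calendar-month arithmetic);
* timestamps at hour resolution; date-only sources (CT, drug tables)
  get hour 00; duplicate (patient, hour) SCr entries keep the smaller
  value (conservative toward non-AKI);
* comparisons carry a 1e-9 guard so binary floating point reproduces
  by-hand decimal arithmetic on two-decimal laboratory values
  (1.3 − 1.0 must not exceed 0.3; 2.1/0.7 must reach ratio 3.0). The
  guard is nine orders of magnitude below measurement resolution and
  cannot change a decision on real-valued data;
* urine output and dialysis initiation are out of scope by design.

The ground-truth label of a feature row evaluates each horizon value
against the references fixed at *t*; the first trigger freezes the
baseline and staging runs from that value onward. The baseline does not
update inside the horizon — the simplest reading consistent with the
staging definition.

## Feature construction

One row per eligible SCr measurement. A row is skipped when (a) either
SCr history window ([−180 d, −30 d) or [−30 d, 0)) is empty — both
windows' statistics are mandatory features and temporal features are
never imputed; (b) the horizon [t+1 h, t+14 d) holds no measurement —
the target would be undefined; or (c) neither reference SCr exists —
the label would be undecidable. Skips are counted per rule in the run
provenance.

Window statistics use the population (n-denominator) standard
deviation; delta-delta is the recent-window delta minus the
older-window delta (acceleration toward the present). Under the 1/SCr
transform the current SCr, all window statistics and the target are
computed on the inverted scale, with min/max recomputed there; the
horizon minimum of 1/SCr equals the inverse of the horizon maximum
exactly (monotone map, same element). Oral chemotherapeutics contribute
per-class counts (mirroring the IV handling) rather than booleans.

Post-processing winsorizes each column at its 2nd/98th percentile
(linear-interpolation percentiles, the numpy default) and z-scores with
the population sd; constant columns map to zeros rather than dividing
by zero. Parameters are reusable on held-out data; nested CV offers a
leakage-safe mode that fits them per outer-train fold, alongside the
default whole-matrix mode that mirrors post-processing before CV.
Winsorize-then-z-score is idempotent on its own output only up to the
gap between adjacent order statistics at the percentile (re-fitted caps
interpolate just inside the previous ones); the test suite checks it at
that tolerance.

Inverting a 1/SCr prediction floors the regressor output at
1/(SCr cap) with a default cap of 20 mg/dL, so non-positive or tiny
predictions map to a finite physiologic ceiling instead of exploding;
floor events are logged.

## Preprocessing

Pipeline order is fixed: patient exclusions → named variable drops →
missing-rate drop → imputation → encoding.

* **Exclusions** remove patients on maintenance dialysis *or* with an
  initial eGFR < 15 mL/min/1.73 m² (strict), i.e. severe chronic kidney
  disease at baseline; either condition suffices. eGFR uses the 2009
  CKD-EPI equation on the recorded first value when present, otherwise
  on the initial SCr with the age at that measurement; the race
  coefficient is off by default and exposed as a flag.
* **Variable filtering** drops three named lists (non-informative,
  dialysis-linked, redundant) and then any variable whose missing rate
  is strictly above 0.4.
* **Imputation** is multiple imputation by chained equations: sklearn's
  IterativeImputer (Bayesian-ridge chained equations with posterior
  sampling) run `n_imputations` times (default 100) with distinct
  sub-seeds; missing numeric cells get the mean over runs, non-numeric
  cells the nearest valid level of the rounded mean code. Observed
  cells are never altered. Averaging many posterior draws trades
  between-imputation variance for a stable point estimate, which is the
  intended use here (a completed table for regression, not Rubin-rule
  inference).
* **Encoding**: booleans → {0,1}; categoricals → integer codes from a
  stable sorted-label map (one column per variable; one-hot available
  behind a flag); dates → days since 1970-01-01. The map serializes to
  JSON and raises on unseen categories at transform time.

By default imputation runs once on the full table before CV (matching
the regression-first architecture the pipeline follows); the
leakage-safe CV mode confines the squeeze/z-score parameters to
training folds, and fold-level imputation can be had by running the
imputer inside a user pipeline.

## Models and nested cross-validation

Roster: linear regression, ridge, lasso, LARS, SGD, random forest;
MARS joins when a py-earth backend is importable, and the roster
shrinks with a warning otherwise — no result in this package depends on
MARS. Default grids are the package's own (none are prescribed
anywhere): ridge/lasso α ∈ {0.01, 0.1, 1, 10}; LARS nonzero
coefficients ∈ {5, 10, all}; SGD α ∈ {1e-4, 1e-3} × {l2, l1}; random
forest 100 trees × depth {unbounded, 10}. The forest grid is kept
small because tree count beyond 100 changed nothing measurable on
synthetic cohorts while tripling cost; any grid can be passed through
`ModelSpec`/`TunedRegressor`.

Nested CV uses k = 3 in both loops. The inner loop selects
hyperparameters by mean validation MSE on the working (possibly
inverted) target scale — the quantity the regressors optimize;
classification metrics are reported but never drive selection. Fold
assignment is deterministic in the seed, identical across models, and
by-row by default, with a by-patient grouping option (row-level splits
let a patient's rows straddle folds, which leaks identity; the default
mirrors splitting "the entire dataset", the grouped mode is the
conservative alternative). Stochastic learners receive sub-seeds
derived from the global seed, making reports bit-for-bit replayable.

Metrics: MSE/MAE on the SCr scale; 4-class stage precision/recall/F1
support-weighted over the classes present in the truth (stage 0
dominates; macro averaging is a flag); binary occurrence
precision/recall/F1 on stage > 0. Zero-denominator ratios score 0 and
are flagged via support counts. A prevalence-matched random-guessing
baseline (precision = recall = F = prevalence, in expectation) anchors
the occurrence scores. The across-years evaluation assigns rows to
three calendar intervals by their measurement date (the first
interval's printed end date "11/31" does not exist and is read as
Nov 30, end-inclusive) and reruns the CV pipeline per interval.

## Synthetic cohort generator

The generator is a test instrument: it reproduces the statistical
structure the method assumes, with ground truth, and does not imitate
any real cohort's distributions. Defaults, chosen once:

* **Demographics** — 60% male; age at registration uniform 30–80;
  registration uniform over the study window (2004–2013) less the
  follow-up; follow-up 2 years.
* **Baseline SCr** — uniform on the adult normal ranges, 0.8–1.3 mg/dL
  (male) and 0.6–1.1 (female), plus a slow sinusoidal drift of
  0.05 mg/dL amplitude and i.i.d. measurement noise (sd 0.03 mg/dL,
  values rounded to two decimals and floored at 0.05).
* **Sampling** — gaps drawn from 1–3 d (inpatient) or 14–180 d
  (outpatient); the regime persists with probability 0.8 per step, so
  dense stretches alternate with sparse follow-up and every gap lies in
  the union of the two ranges.
* **Episodes** — base hazard 0.8/patient-year, multiplied by 3.0 for
  30 days after any drug/chemotherapy exposure (inhomogeneous-Poisson
  thinning, ≥ 60 d between onsets). Each episode rises linearly to its
  peak over 48 h and decays exponentially (τ = 4 d, full recovery in
  about two weeks). Peak ratios are drawn from guard-banded intervals
  inside the staging bands — [1.60, 1.80], [2.10, 2.80], [3.15, 3.70]
  for stages 1/2/3 — so that measurement noise cannot move a peak
  across a band edge; a measurement is guaranteed at the peak and
  within the preceding three weeks, making every episode decidable by
  design. Without that guarantee the criteria legitimately miss
  episodes and no clean oracle exists.
* **Exposures** — Poisson counts per follow-up year: CT 3.0, IV-chemo
  courses 2.0 (three weekly doses each), oral prescriptions 1.5,
  nephrotoxic prescriptions 1.0 with 3–14 day durations expanded to
  daily coverage.
* **Non-temporal table** — ~40 variables with realistic types and mild
  correlations (BMI from height/weight, diastolic from systolic
  pressure, hemoglobin by sex, urea tracking baseline SCr), masked
  missing-at-random with per-variable rates; a few rates sit above the
  0.4 threshold on purpose so the missing-rate drop rule has work to
  do. 2% of patients are on maintenance dialysis and 2% carry severe
  CKD baselines (SCr 4–6 mg/dL), exercising the exclusion rules.

What the generator does **not** emulate: real between-patient
heterogeneity of trajectories, informative (non-random) measurement
timing, correlated multi-morbidity, lab batch effects, or any actual
cohort's Table-1 distributions. Passing tests therefore demonstrate
correctness of the machinery and learnability under the stated
assumptions — not clinical performance on real data.

## Problem sizes and determinism

The shipped tests and the acceptance script use 200-patient cohorts for
criteria-recovery checks and a 500-patient cohort (~6,600 feature rows)
with 10 imputation repeats for the end-to-end forecasting run; these
sizes give stable metrics while keeping a full run in the minutes
range on one CPU. Every random draw — generator, imputation, fold
assignment, stochastic learners — derives from a single seed through
spawned `SeedSequence` children, so identical configuration and seed
reproduce every artifact bit-for-bit on one platform.

## Known limitations

* The staging engine assumes time-sorted, positive SCr values; the IO
  layer enforces both.
* Episode scanning uses a 14-day refractory period after each onset;
  re-detections during a slow recovery tail appear as separate
  episodes only after that window.
* The MICE variant is numeric chained equations with rounded-code
  mapping for categoricals, not predictive-mean matching; with the low
  missing rates left after the 0.4 filter the practical difference is
  the between-run variance, which the 100-fold averaging removes.
* MARS is optional and untested in environments without a py-earth
  backend.
* Interval evaluation reruns CV within each interval; with few rows per
  interval the per-interval metrics are noisy.
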