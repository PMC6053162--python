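# akih — forecasting acute kidney injury from irregular creatinine data

Acute kidney injury (AKI) is a frequent, dangerous complication in
oncology: chemotherapy doses get cut, contrast imaging and nephrotoxic
drugs stack risk, and much of the injury develops *outside* the
hospital, where serum creatinine (SCr) is measured at irregular
intervals ranging from days (inpatient) to several months (outpatient
follow-up). `akih` is a toolkit for that setting. It detects and stages
AKI from creatinine alone, turns irregular longitudinal records into
fixed-length feature vectors, and forecasts each patient's maximum SCr
over the next 14 days — from which the occurrence and stage of imminent
AKI follow.

The package is aimed at clinical-ML researchers and biostatisticians
who want a fully testable reference implementation: every stage of the
method runs on synthetic cohorts with known ground truth, so the whole
pipeline is verifiable without access to any hospital data.

## The method

**Detection and staging (modified KDIGO, SCr-only).** Two reference
values anchor each evaluation time *t*: the *initial* SCr (the smaller
of the first measurement within ±2 months of cancer-registry
registration and the first after registration) and the *recent* SCr
(the minimum over the 3 weeks before *t*). AKI is detected when the
current SCr exceeds 1.5× either reference, or exceeds it by more than
0.3 mg/dL (both strict). The triggering reference becomes the
*baseline* b. Over the two weeks from onset, with M the maximum SCr:

- stage 3 if M/b ≥ 3.0 or M ≥ 4.0 mg/dL;
- stage by ratio: M/b ∈ [1.5, 2.0) → 1, [2.0, 3.0) → 2, ≥ 3.0 → 3;
- stage by increment: 1 if M − b > 0.3 mg/dL;
- stage = max(stage by ratio, stage by increment).

Urine-output and dialysis-initiation criteria are deliberately out of
scope.

**Featurization.** One feature vector per eligible SCr measurement:
the preprocessed non-temporal patient variables plus 26 temporal
features — current SCr, age, {mean, sd, min, max, delta} of SCr over
[−180 d, −30 d) and [−30 d, 0), a delta-delta term, CT-scan counts and
IV-chemotherapy counts per nephrotoxicity class over [−45 d, −15 d) and
[−15 d, 0), ACEi/ARB and diuretic exposure flags and per-class oral
chemotherapy counts over [−30 d, 0). The target is max SCr over
[t+1 h, t+14 d). Because SCr and kidney function are inversely related,
an optional 1/SCr transform is applied coherently to the current SCr,
all SCr window statistics and the target (min 1/SCr = 1/max SCr).
Features are winsorized at the 2nd/98th percentiles and z-scored.

**Models and evaluation.** Linear regression, ridge, lasso, LARS, SGD
and random forest (plus MARS when a py-earth backend exists) are tuned
and evaluated by nested 3×3 cross-validation: the inner CV selects
hyperparameters by validation MSE, the outer CV gives the unbiased
estimate. Predicted maxima are pushed back through the detection and
staging rules, yielding 4-class stage and binary occurrence
precision/recall/F alongside MSE/MAE on the SCr scale.

**Synthetic cohorts.** `akih.synth` generates patients with
sex-specific baseline SCr in the adult normal ranges, alternating
dense/sparse sampling regimes, exposure events that raise the
subsequent episode hazard, and injected AKI excursions whose
peak-to-baseline ratio sits inside a known staging band — giving exact
ground-truth labels for every downstream component.

## Worked example

```python
from akih import SyntheticConfig, generate_cohort
from akih.criteria import detect_cohort_episodes
from akih.preprocess import preprocess_cohort, PreprocessConfig
from akih.features import build_feature_matrix, make_postprocessor, FeatureMatrix
from akih.models import nested_cv, CVConfig

cohort, truth = generate_cohort(SyntheticConfig(n_patients=200, seed=7))
episodes = detect_cohort_episodes(cohort)
cohort, numeric, emap, report = preprocess_cohort(
    cohort, PreprocessConfig(n_imputations=10, seed=7))
fm = build_feature_matrix(cohort, numeric, transform="inverse")
post = make_postprocessor().fit(fm.X)
fm = FeatureMatrix(X=post.transform(fm.X), y=fm.y, meta=fm.meta,
                   transform="inverse")
report = nested_cv(fm, "ridge", CVConfig(seed=7))
```

prints, step by step:

```
patients: 200 | SCr measurements: 5823
AKI episodes detected: 349 | injected: 349
after exclusions: 191 | model variables: 22
feature rows: 2943 | AKI prevalence: 0.312
ridge (1/SCr): MSE 0.2552 MAE 0.2675 | occurrence P 0.6814 R 0.6081 F 0.6410
```

All 349 injected episodes are recovered by the detection rules; nine
patients are excluded (maintenance dialysis or initial eGFR below
15 mL/min/1.73 m² by the 2009 CKD-EPI equation); 2,943 feature rows are
materialized after the skip rules; and nested CV scores the ridge
forecaster on held-out folds. A 14-day-ahead occurrence F of 0.64
against a 0.31 random-guessing prevalence baseline shows the windowed
features carry real signal.

The same pipeline is available from the shell:

```sh
akih simulate --n-patients 200 --seed 7 --out cohort/
akih run --config config.yaml --out runs/demo
```

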