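# mobiward

Objective monitoring of in-hospital patient mobilization from wearable
accelerometers. The package implements the full analysis chain used to
quantify postoperative recovery on a cardiac-surgery ward:

1. **Signal processing** — dual-site tri-axial acceleration (right upper
   arm + right upper leg, units of g) is resampled to a canonical 100 Hz,
   split into *total* and *dynamic* (body) acceleration with a 0.8 Hz
   high-pass filter, and cut into 256-sample (2.56 s) windows.
2. **Feature bank** — each window pair maps to an ordered vector of 160
   features (per site and axis: mean, RMS, autocorrelation peaks, six
   spectral peaks, five band powers, median, SD, MAD; plus per-site mean
   signal magnitudes).
3. **Feature selection** — diagonal-metric neighbourhood component
   analysis (NCA) fitted by SGD (≤ 30 epochs); features with weight ≥ 0.1
   are kept.
4. **Classification** — a feed-forward network (one hidden layer, 18 tanh
   units, softmax output) assigns each window one of six activities:
   lying in bed, sitting, standing (static) and walking, cycling, walking
   stairs (dynamic). Classes are balanced by seeded down-sampling before
   training.
5. **Validation** — stratified 10-fold and leave-one-subject-out (LOSO)
   cross-validation with per-activity recall/precision, subject-count
   learning curves, and a single-sensor (arm-only / leg-only) ablation.
6. **Ward analysis** — classified windows are aggregated into daily
   activity minutes and percentages between 7 a.m. and 11 p.m., and
   day-to-day recovery is modelled per activity with the linear mixed
   model

   Y_ij = β0 + β1·male_i + β2·(day_ij − 1) + b_i + ε_ij,

   fitted by maximum likelihood with a patient-level random intercept b_i.
   β2 is the recovery signal (e.g. minutes of bed rest lost per hospital
   day), β1 the male–female contrast.

Because no patient recordings are distributed, a first-class
`synthetic` module generates the three kinds of study data — 30 s-per-activity
calibration sessions, full ward-day recordings with ground truth, and
mixed-model daily-summary cohorts — so every stage is testable end to end.

## Worked example

```python
from mobiward import (
    generate_cohort_sessions, build_dataset, kfold_cv, loso_cv,
    CohortSpec, generate_daily_summaries, fit_activity_trend,
)

# six-activity calibration corpus: 31 subjects, 30 s per activity, 100 Hz
sessions = generate_cohort_sessions(n_subjects=31, seed=1)
dataset = build_dataset(sessions)          # 50% overlapping windows
print(dataset.features.shape)              # (3999, 160)

report = kfold_cv(dataset, k=10, seed=0)   # NCA + ANN refit per fold
print(f"10-fold pooled accuracy {report.pooled.accuracy:.1f}%")
# 10-fold pooled accuracy 100.0%

report = loso_cv(dataset, seed=0)          # 31 folds, one per subject
print(f"LOSO pooled accuracy {report.pooled.accuracy:.1f}%, "
      f"worst per-activity metric {report.pooled.min_recall_precision():.1f}%")
# LOSO pooled accuracy 100.0%, worst per-activity metric 100.0%

# recovery modelling on a simulated 29-patient cohort
summaries = generate_daily_summaries(CohortSpec(seed=0))
fit = fit_activity_trend(summaries, activity=1, scale="minutes")
print(f"lying-in-bed slope {fit.beta2:.1f} min/day "
      f"(95% CI {fit.ci['time'][0]:.1f} to {fit.ci['time'][1]:.1f}), p={fit.p_time:.2g}")
# lying-in-bed slope -43.9 min/day (95% CI -51.9 to -35.8), p=9.2e-27
```

The LOSO accuracy is the deployment-relevant number: all of a subject's
windows are held out together, so it measures generalization to a person
the network never saw. The 10-fold figure is optimistic in comparison
because windows of one subject appear on both sides of the split. The
mixed-model slope is the clinical endpoint: a negative lying-in-bed slope
of tens of minutes per day quantifies progressing mobilization.

A command-line interface mirrors the library
(`mobiward simulate|extract|select|train|validate|classify|summarize|trend`);
run `mobiward --help`.

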