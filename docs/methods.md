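# Methods

This note documents the models and procedures implemented in `mobiward`,
the defaults that matter, what the synthetic data does and does not
emulate, and the numerical choices made where the design was open.

## Signal model and preprocessing

A wrist-free dual-site setup is assumed: one tri-axial accelerometer on
the right upper arm, one on the right upper leg, both reporting in units
of g. The raw signal is the sum of a gravitational component (segment
orientation — identifies static postures) and an inertial component
(cyclical body acceleration — identifies dynamic activities).

- **Canonical rate, 100 Hz.** All traces are resampled on ingest by linear
  interpolation so that one 256-sample window always spans 2.56 s, roughly
  two steps at an average walking cadence. Upsampling by more than 4× is
  refused rather than fabricating bandwidth. Inputs in m/s² can be
  converted with a config flag (`input_units`).
- **Gravity/body separation.** The *dynamic* signal is the per-axis
  high-pass output at a 0.8 Hz cutoff; the *total* signal is kept
  unchanged. The filter family, order and phase handling are open design
  parameters; the defaults are a 4th-order Butterworth applied
  forward–backward (zero phase), because zero-phase filtering cannot shift
  the signal relative to its activity labels. Reflect padding handles the
  edges; traces shorter than three filter transients are refused. All
  three choices are config-exposed (`filter.*`).
- **Windowing.** Windows are cut on the common time span of the two sites
  after nearest-sample alignment (residual offsets below half a sample
  period are ignored). Training uses 50% overlap; continuous postoperative
  classification uses non-overlapping windows. The window count follows
  `floor((N − 256)/step) + 1` with `step = round(256·(1 − overlap))`;
  trailing partial windows are dropped, and windows inside the first/last
  second are flagged (filter transients), not dropped.
- **Labelling rule.** A training window receives a label only when a
  single labelled interval covers its entire span (`min_coverage = 1.0`),
  which excludes activity-transition windows — the main source of label
  noise.

## Feature bank (160 features)

Per site (arm, leg) and axis (x, y, z), 26 features are computed from the
total and dynamic signals of one window: mean and median of total;
RMS, SD and MAD of dynamic; MAD of total; the autocorrelation main peak
r(0) plus the height and lag of the dominant non-zero-lag peak (a cadence
estimator); the heights and positions of the first six spectral peaks; and
the power in five adjacent bands. Two magnitude features per site (mean
Euclidean norm of total and of dynamic) complete the bank:
2·3·26 + 2·2 = 160.

Numerical choices:

- Spectral estimates use a single-taper (Hamming) periodogram of the
  *dynamic* signal — on the total signal the gravity DC line would
  dominate every spectrum. Peaks are local maxima sorted by height,
  zero-padded with (0, 0) if fewer than six exist.
- The five band edges default to 0.5, 5, 10, 15, 20, 25 Hz ("predefined"
  adjacent bands covering the locomotor range below the 100 Hz Nyquist);
  both edges and taper are config-exposed (`spectral.*`).
- The autocorrelation is biased (1/n) and normalized by r(0); the second
  peak is searched from the first non-positive lag onward. Zero-variance
  signals return the degenerate (0, 0).
- MAD is the unscaled median absolute deviation about the median.
- The feature order is frozen in `features.FEATURE_NAMES`
  (`{site}_{axis}_{feature}` then `{site}_mag_*`), so selection masks are
  portable and site ablations are column masks.

Scale behavior is tested: scaling all accelerations by a > 0 scales
amplitude-like features by a, power-like features by a², and leaves peak
positions and lags unchanged.

## NCA feature selection

Feature selection maximizes the smooth leave-one-out objective of
neighbourhood component analysis with a diagonal metric
`d(x_i, x_j) = Σ_r w_r² |x_ir − x_jr|`, ridge-regularized with λ = 1/n by
default, by per-sample stochastic gradient ascent: weights start at 1,
learning rate 0.1 decaying as 1/(1 + t·decay) with decay = 1e-4 (slow
decay — the regularizer needs sustained step mass to pull uninformative
weights toward zero within the 30-epoch budget), at most 30 epochs with an
early exit when the epoch objective stalls. Features with |w| ≥ 0.1 are
kept; the threshold is config-exposed and `threshold_sweep` reports the
selected count as a function of it.

Two scalability/robustness choices:

- For large training sets the fit runs against a seeded class-stratified
  reference subsample (default cap 500 samples), keeping the per-epoch
  cost O(m²p) with m bounded. Selection quality on the synthetic corpus is
  unaffected (≈ 60 of 160 features survive).
- Standardization parameters (computed on the training fold) are stored
  with the result and reused at prediction time; unstandardized input is
  detected, warned about and standardized internally.

A caveat documented by the shuffled-label test: with uninformative labels
the weight dynamics are a multiplicative random walk with a negative
drift, so most weights fall below the threshold but a stochastic tail can
survive; selection counts on pure noise are small, not exactly zero.

## Classifier

A feed-forward network with one hidden layer of 18 tanh units and a
softmax output over the six activities, trained with cross-entropy
(scikit-learn `MLPClassifier`, adam). 15% of the training samples are held
out for early stopping with patience 10 and at most 500 epochs. Small
minibatches (32) and an initial learning rate of 0.01 ensure enough
optimizer steps per epoch that the 10-epoch patience is meaningful even on
small folds. Everything is deterministic given the seed. Ties in the
softmax break toward the lowest activity code.

Training sets are first balanced by seeded uniform down-sampling of every
class to the smallest class count. On a ward, static postures outnumber
dynamic activities roughly 3:1; an alternative mode
(`balance.static_dynamic_ratio`) caps static classes at a chosen multiple
of the smallest dynamic class instead.

Balancing and selection run inside each cross-validation training fold
(no leakage); a `select_once` config flag performs selection once on the
full dataset instead, for comparison with select-once protocols. Balancing precedes the
early-stopping split; windows of one subject can share a fold in K-fold
CV, which is exactly the intra-subject contamination LOSO is meant to
expose.

No temporal smoothing is applied to classified timelines — windows are
classified independently; an optional width-3 majority filter exists but
is off by default.

## Ward analysis

Daily summaries count classified non-overlapping windows whose *start*
falls in [07:00, 23:00) local time: each window contributes 2.56/60 min
to its activity, so a fully observed day has 960 min and
Σ minutes = observed minutes by construction. Days with no windows in the
span report zero observed minutes and absent percentages. Partial first
days (ICU discharge mid-morning) are retained; the percentage scale is
the more comparable one there.

The recovery model per activity and scale (minutes, percentage) is

    Y_ij = β0 + β1·male_i + β2·(day_ij − 1) + b_i + ε_ij,
    b_i ~ N(0, σ_b²), ε_ij ~ N(0, σ²),

fitted by maximum likelihood (not REML) with Wald 95% CIs and p-values
(statsmodels `MixedLM`). Day 1 is coded as time 0, so β0 is the female
Day-1 mean. The random-effects structure is a patient-level random
intercept — the simplest structure identified by cohorts of this size;
additional patient-day covariates (e.g. anthropometrics) can enter as
fixed effects via `covariates=`. Non-convergence is flagged on the result
object rather than raised, so a 12-response report never dies on one
degenerate response.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of the study data, not its
biomechanics:

- **Calibration sessions.** Six 30 s blocks (protocol order stand, sit,
  lie, walk, cycle, stairs) at 100 Hz. Static postures are a site-specific
  gravity orientation plus white sensor noise (SD 0.02 g); dynamic
  activities add a cadence fundamental and two harmonics. Orientations are
  chosen so the arm separates lying from sitting and the leg separates
  sitting from standing — the stated rationale for instrumenting both
  segments. Cadences: walking 1.8 Hz, stairs 1.4 Hz, cycling 1.2 Hz.
  Stairs differ from walking structurally (larger leg excursion, a
  pronounced vertical second harmonic, near-quiet arm), so the arm/leg
  amplitude ratio and harmonic profile discriminate even when personal
  cadences overlap.
- **Inter-subject variation.** Per subject and site: a random small sensor
  re-orientation (SD 8°), a personal cadence factor (SD 6%) and a personal
  amplitude factor (SD 15%). These values were fixed once as plausible
  magnitudes of attachment and gait variability.
- **Ward days.** Scheduled activity blocks stitched with 2 s linear
  cross-fades starting 07:00; transition windows carry no ground-truth
  label, mirroring the transfer-misclassification caveat of real
  deployments.
- **Cohorts.** 29 patients (22 male, 7 female), ward-stay nights drawn
  from a discrete distribution with median 5 and IQR 3–6, observation
  capped at 7 days. Daily lying-in-bed minutes follow the mixed model
  with fixed effects (413, +11 male, −41 per day); standing, walking,
  cycling and stairs follow their own small fixed effects; sitting takes
  the remainder of the complete 960-min day so conservation holds exactly.
  Variance components are not published for the original cohort; the
  defaults σ_b = σ = 70 min for lying (smaller for the minor activities)
  were chosen once to be consistent with the printed interval widths while
  keeping truncation at the [0, 960] bounds negligible.

Not emulated: soft-tissue artifacts, sensor repositioning drift, support
walking (walker/therapist), realistic gait waveforms, or correlations
between a patient's activities beyond the day-total constraint. Passing
the closed-loop tests therefore demonstrates that the pipeline machinery
is correct and that the two-site geometry and cadence structure suffice
for separation — not that these accuracies transfer to real patients.

## Problem sizes and determinism

The corpus-level checks use the full study-sized configuration:
31 calibration subjects (≈ 4,000 windows × 160 features), 10-fold and
31-fold LOSO cross-validation with selection and training refit per fold,
and 200 replicate cohorts for slope recovery. Cheaper closed-loop tests
(single-sensor ablation ordering, ward-day classification) run on 8–10
subject corpora, where the behavior is structurally identical. Every
random element — generators, subsampling, fold shuffling, SGD, network
initialization — is driven by explicit seeds, and identical seeds
reproduce results bit-for-bit.

## Known limitations

- The NCA selected-set identity is not comparable to any published list;
  only its cardinality behavior and downstream accuracy are meaningful.
- K-fold results on the synthetic corpus inherit intra-subject
  contamination by design (that is what the scheme measures).
- The mixed model assumes Gaussian errors and a linear day trend;
  truncation at 0/960 min mildly biases slopes for activities near the
  bounds if variances are set much larger than the defaults.
- The CLI serializes trained pipelines with pickle; archives are only
  portable across matching library versions.
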