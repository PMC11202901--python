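# Methods

## Scoring rules

**Impaired-run detection.** A frequency position on the 8-point grid
(0.125, 0.25, 0.5, 1, 2, 3, 4, 8 kHz) qualifies when its threshold is
present and ≥ 30 dB HL (configurable). The impaired run is the longest
contiguous block of qualifying positions of length ≥ 3; ties between
equally long runs go to the one starting at the lowest frequency. Isolated
qualifying positions outside the selected run are excluded. Missing
thresholds never qualify — a conservative choice that can split a run and
push a borderline patient into the "no qualifying run" exclusion.

**Siegel grading.** Complete: one-month mean ≤ 25 dB, regardless of gain.
Partial/slight: gain strictly greater than 15 dB with one-month mean in
(25, 45] / (45, 75]. Everything else is none. The band edges are inclusive
upper bounds, matching the inclusive "25 dB or lower" style of the
complete rule; a gain of exactly 15 dB grants nothing, preserving the
strict "> 15 dB" wording of the two recovery-granting rules. *Recovered*
means complete or partial. The traditional variant averages the fixed
0.5/1/2/3 kHz band; the personalized variant averages the detected run,
applied identically to the affected and unaffected ears.

**Severity categories.** Half-open 20-dB bands on the mean threshold:
< 40 mild, [40, 60) moderate, [60, 80) severe, [80, 100) profound, ≥ 100
deaf. The half-open convention is forced by the "deaf ≥ 100 dB" end of the
scale.

**Audiogram shape.** Clinician shape-typing has no published rulebook, so
the package uses a deterministic band-mean heuristic: low = mean(0.125–0.5),
mid = mean(1–2), high = mean(3–8 kHz); *deaf* when the overall mean is
≥ 90 dB, *flat* when the three band means sit within a 10-dB spread,
*ascending*/*descending* when the low/high band exceeds the opposite band
by more than 10 dB, *u_shaped* when the mid band exceeds both edges by
more than 10 dB, with *flat* as the fallback. Rules are evaluated in that
order, which resolves overlapping profiles deterministically.

## Exclusion cascade

Five rules, applied sequentially with each patient removed at the first
rule it violates: duplicate record; missing one-month affected-ear
audiometry; missing initial audiometry in either ear; bilateral disease;
no qualifying impaired run. Per-rule counts are order-dependent; the final
membership is not (any patient violating at least one rule is always
removed), and the cascade accepts an explicit rule order so this property
can be exercised.

## Assessment-shift statistics

The primary test is a Pearson χ² without continuity correction on the 2×2
table of (variant × recovered), treating the two assessments of the same
patients as independent samples — this is the analysis convention the
package reproduces (the reference margins 247/334 vs 220/361 give
χ² = 2.61, p = 0.106; a Yates-corrected statistic would give ≈ 2.42, so
the uncorrected form is the right reading). Because the samples are in
fact paired, an exact McNemar test on the agreement table is exposed as a
clearly-labelled extra; on the same transition structure (34 down, 7 up)
it is strongly significant, a deliberate illustration of how much the
pairing matters.

Group comparisons gate on a Shapiro–Wilk normality test per group
(α = 0.05): normal continuous variables get Welch's t-test and mean (SD)
summaries, the rest Mann–Whitney U and median (Q1, Q3). Categorical
variables get a χ² on the level × group table, with Fisher's exact test
when a 2×2 table has an expected cell below 5. No multiplicity correction
is applied, matching the descriptive intent of the table.

## Synthetic cohort generator

The generator emulates the *structure* the analysis needs, not any real
patient: a latent prognosis score in [0, 1] (stratum mean 0.25 or 0.75,
SD 0.10) drives everything. The recovery-leaning stratum is drawn with
probability 0.379 — the published personalized-criteria recovery rate —
and selects stratum-conditional distributions: the published audiogram
shape mix, log-normal initial severities matched to the published
median/quartiles (75.63 (56.77, 98.44) vs 61.25 (48.33, 77.34) dB),
unaffected-ear levels likewise, and the published recovered vs
non-recovered contrasts for age, dizziness, hypertension, diabetes,
tinnitus, laboratory values and treatment delay. Covariates without
published contrasts use field-plausible shared values. Continuous families
are normal or log-normal matched to median and IQR by quantile matching
(quartiles at ±0.674σ).

Audiograms are built from shape templates around the severity target in
5-dB steps and redrawn until the shape classifier round-trips and a
qualifying run exists. One-month thresholds shrink the loss above a
per-frequency pre-morbid floor (the better of the unaffected-ear threshold
and 20 dB) by a recovered fraction g ~ N(−0.05 + 1.1·latent, 0.12) clipped
to [0, 1], plus 2 dB measurement noise, never exceeding initial + 5 dB.
The intercept/slope pair was calibrated once so the *emergent* recovery
rate — labels are always recomputed from the audiograms by the Siegel
scorer, never planted — sits at the 0.379 target (measured 0.371–0.386 at
n = 5000 across seeds), then frozen.

Missingness is injected MCAR at per-feature rates taken from the published
missing-value percentages where available (e.g. triacylglycerol 40.1%,
treatment delay 39.9%, urea nitrogen 12.05%); audiometric summary features
and the outcome are never masked. Exclusion-cascade violations are planted
in configurable per-rule counts on top of the clean cohort, each
constructed to violate exactly its own rule.

What the generator does **not** emulate: real joint dependence among
covariates beyond the single latent score, informative (MNAR) missingness,
longitudinal audiometry beyond the two time points, and measurement
artifacts such as vibrotactile responses at high intensities. Tests
passing on this cohort therefore demonstrate correctness of the *methods*
under the stated generative assumptions, not clinical performance on real
data.

## Preprocessing

Imputation is round-robin chained equations with a ridge-regularized
linear model per feature (stable under collinearity), visiting features
from fewest to most missing, median-initialized, capped at 20 cycles with
convergence tolerance 1e-3 on each feature's scale; binary and integer
features are imputed on the linear scale and then rounded half-away-from-
zero (binaries additionally clipped to {0, 1}) before min–max scaling.
Constant features scale to 0; held-out values may fall outside [0, 1] (no
clipping). Imputer, scaler and tuning decisions are functions of training
rows only, asserted by mutation probes in the tests.

The split plan is a stratified 80/20 train/test split, 10 independently
shuffled stratified 5-fold partitions of the training set for validation
(50 cycles), and 3-fold stratified tuning folds. "Ten combinations" is
read as 10 repeats with different shuffle seeds; the 80/20 split is
stratified by outcome so the test-set arithmetic (117 patients, 44
positives at the reference margins) is stable.

## Models and evaluation

Hyperparameters are tuned once on the full training partition by
exhaustive grid search maximizing mean AUROC over the 3 tuning folds (ties
break first-in-grid); the validation cycles then refit preprocessing and
all models per cycle with those parameters. The shipped default parameter
set is the tuned optimum of the reference protocol, so the expensive
search can be skipped (`params="optimal"`). Inverse-class-frequency
weighting applies to the five families that support it natively (logistic,
tree, forest, SVM, LightGBM); AdaBoost, XGBoost and KNN run unweighted.
The linear SVM's margins are turned into probabilities by Platt sigmoid
calibration fitted on training-internal folds, since soft voting — the
unweighted mean of the eight positive-class probabilities — needs
calibrated outputs. The decision threshold is 0.5 with ties classified
positive.

Metrics come from the confusion matrix (balanced accuracy, recall,
precision, F1; undefined ratios reported as missing, never as 0) and the
trapezoid AUROC, which the tests pin to the exhaustive pairwise-concordance
oracle. Test-phase AUROC CIs are stratified-bootstrap percentile intervals
(2000 resamples, seeded); validation-phase CIs are percentile intervals
over the per-cycle AUROC values, matching the "average over all cycles"
reporting convention.

## Attribution

The ensemble is heterogeneous, so attributions use a model-agnostic
permutation-sampling Shapley estimator on the probability scale: each
random feature ordering is paired with one background row sampled from the
training partition, and the telescoping walk from background to explained
row yields exact per-row local accuracy (attributions sum to prediction
minus mean sampled-background prediction) regardless of the number of
permutations. Defaults: 100 background rows by seeded subsampling, 24–32
permutations, top-20 ranking by mean absolute value with a
correlation-sign direction summary.

## Problem sizes and numerical choices

The shipped test-suite and acceptance runs use a 581-patient cohort with
2 × 5-fold validation and the reference hyperparameters, a 5000-patient
draw for calibration checks, and reduced bootstrap/permutation counts —
sizes chosen so the whole analysis re-runs on a single CPU in minutes
while leaving the statistical assertions well-powered. The full 10 × 5
protocol and the 2000-resample bootstrap remain the package defaults for
real use. The null condition for model evaluation is seeded label
permutation: the PTA-average features are mechanically coupled to the
Siegel rules, so no feature-generating configuration can make labels
exactly independent of the features — permutation is the exact null.

## Known limitations

- The shape heuristic is a stand-in for clinician judgement; its
  five-way split is deterministic but not validated against experts.
- Single imputation per run (no Rubin pooling across multiple completed
  datasets).
- Severity interacts with treatment assignment only through one planted
  conditional; real treatment allocation is far more confounded.
- The generator's recovery-rate calibration holds at the default
  configuration; moving gain or severity parameters requires
  recalibration.
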