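# Methods

## Synthetic cohort model

Each subject's ROI time series is piecewise-stationary Gaussian.  Time is
partitioned by the union of all effect-epoch boundaries; within a segment
[t₀, t₁) the rows are x_t = L z_t with z_t ~ N(0, I_N) and L the Cholesky
factor of the segment's target correlation matrix C.  Controls always use
the baseline structure (identity plus any configured baseline edge
correlations); patients use baseline + Δr on each effect edge during its
epoch.  A non-positive-definite target (conflicting planted edges) is
rejected with the offending edge set named.

The series are then band-limited with a zero-phase 4th-order Butterworth
band-pass (default 0.01–0.1 Hz at TR = 2 s, i.e. the conventional
resting-state band; `band_limit=False` disables it for exact-correlation
unit tests).  Because every region passes through the same linear filter,
the zero-lag correlation structure inside a stationary segment is
preserved; epoch boundaries are smeared over the filter's memory, which
slightly softens the planted on/off transitions.  A periodogram check in
the test suite verifies >90 % of signal variance lies inside the band.

Order of operations is correlate-then-filter: imposing the correlation on
white innovations and filtering afterwards keeps the planted within-epoch
correlation interpretable, at the cost of the boundary smearing above.

Defaults mirror a typical depression cohort: 43 patients / 56 controls,
T = 200 timepoints, TR = 2 s, N configurable (30 for desk-scale work; the
N = 273 configuration reproduces the full-scale feature arithmetic
76 × 37,128 = 2,821,728 but is slow on one core).  Labels are +1
(patient) / −1 (control).  Covariates are drawn per group — male rate
13/43 vs 30/56, education 11.44 ± 3.33 vs 15.78 ± 4.33 years — so gender
and education are genuine confounds.  Clinical scores exist for patients
only (HAMD 23.35 ± 3.33, HAMA 18.04 ± 3.33 when uncoupled); a coupling
replaces a score by intercept + c·v + N(0, σ), where v is the subject's
mean windowed correlation of a designated edge over a designated window
range.  The implied population correlation c·sd(v)/√(c²sd(v)² + σ²) has
no closed form (sd(v) depends on windowing and filtering), so recovery
tests estimate it with a large-n Monte-Carlo oracle; the default coupling
(c = −8.5, σ = 2) was calibrated that way to an implied r ≈ −0.6.

What the generator does **not** emulate: hemodynamics, head motion,
physiological noise, spatial autocorrelation between neighboring regions,
non-Gaussian marginals, and slow nonstationarities other than the planted
epochs.  Passing tests therefore show that the pipeline recovers
transient second-order structure from band-limited Gaussian data — not
that it would survive fMRI artifacts; on real data the preprocessing that
removes those artifacts is assumed upstream.

## Connectivity features

Windows are half-open, 0-based [kh, kh+w), rectangular (no taper), with
W = ⌊(T−w)/h⌋ + 1.  Feature values are raw Pearson r (a Fisher-z flag
exists, default off, since the classifier consumes correlations directly).
Ordering is window-major then row-major upper triangle, and the
column ↔ (window, i, j) map is an exact bijection (property-tested).
Static connectivity is the W = 1, w = T special case, computed by the same
code path.  Windows are reported 1-based in output tables; window k spans
[k·h·TR, (k·h+w)·TR) seconds.

## Screening

Features are first residualized on intercept + gender + education by
least squares; the fitted adjustment (training means and coefficients) is
stored so held-out subjects are adjusted by the training fit.  Constant
covariates are dropped (degenerate designs reduce to centering); genuinely
collinear designs are rejected.  The two-sample t-test is pooled-variance
by default (Welch by flag); degenerate zero-pooled-variance columns get
p = 1 and are never retained.

A calibration subtlety found during validation: when a covariate is
itself group-imbalanced (education here), regressing it out removes part
of the group-contrast direction from every feature, making the subsequent
t-test conservative — the retained fraction on effect-free cohorts drops
an order of magnitude below α.  The screening machinery itself is exactly
calibrated (verified on iid features).  Calibration experiments therefore
use covariates with matched group distributions (a complete null); the
confounded variant is available behind a flag, and on real analyses the
conservatism only makes screening stricter.

Screening scope is a protocol choice: `full` screens once on all subjects
available to selection (the classical protocol; optimistic when the same
subjects are then cross-validated) and `train_only` refits screening
inside each training fold.  The hold-out protocol quantifies the
difference; see Evaluation.

## Nonlinear SVM-RFE

After training the soft-margin RBF SVM, each surviving feature f is scored
by ΔJ(f) = ½ aᵀK a − ½ aᵀK₍₋f₎ a with a = α ⊙ y on the support vectors and
K₍₋f₎ the kernel without feature f, dual coefficients held fixed.  For the
RBF kernel K₍₋f₎ = K ⊙ exp(γ D_f) with D_f the squared feature-f
differences, so a full ΔJ sweep costs one n_sv × n_sv matrix per feature.
Elimination drops 10 % of survivors per round while more than 100 remain,
then one per round; ties in ΔJ eliminate the lower column index first.
The importance ranking is the reverse elimination order.

The optimal subset size is the argmax (ties → smallest n) of the
cross-validated AUC of the top-n subsets, with the same seeded stratified
fold assignment reused across n.  Note the ranking is computed on all data
available to selection, so this curve is selection-biased upward on pure
noise (mean peak ≈ 0.7–0.8 at n = 40 with 20 noise features) — it is a
subset-size criterion, not an unbiased performance estimate; unbiased
estimates come from the evaluation protocols.  Reported weights are the
selected subset's rank positions rescaled linearly onto [1.00, 0.00].

Hyperparameters (C, γ) come from grid search over the conventional
powers-of-two grids (C: 2⁻⁵…2¹⁵, γ: 2⁻¹⁵…2³, step 2) maximizing stratified
CV accuracy, ties toward the smaller values.  The desk-scale experiments
fix C = 1, γ = 0.05 (≈ 1/n_features at ~100 screened correlation-valued
features); γ far above 1/n_features makes the kernel too local and
degrades the ΔJ ranking noticeably.

## Evaluation

Repeated stratified k-fold CV (default 10 folds, shuffled each round):
within a round all out-of-fold predictions are pooled into one confusion
matrix and one AUC; the report averages rounds and gives across-round SDs.
Sensitivity is on the +1 class, specificity on −1, scores are decision
values, and AUC is the trapezoidal ROC area, which equals the Mann–Whitney
probability of correct ordering with ties counted ½ (cross-checked to
1e−12 against an explicit pair count).  LOOCV is deterministic; a
single-class training fold (the n = 2 edge case) uses a degenerate
constant model that predicts the lone training class, so both held-out
subjects of a 1-vs-1 problem are misclassified — documented, deterministic
behavior.

The hold-out protocol splits subjects stratified (fraction or absolute
test count, e.g. 26 of 99), runs covariate fit → screening → RFE → subset
selection → final fit strictly on the training split, verifies train/test
index disjointness, and applies the frozen pipeline once to the test
split.  The train-side CV estimate honors the screening scope; with
`full` scope on a pure-noise cohort the train CV AUC inflates to ≈ 0.9
while the untouched test split stays at ≈ 0.5 — the selection-before-CV
optimism, quantified.

The permutation-null experiment spreads its 100 CV rounds over 20
independent label permutations (5 rounds each): one permutation fixes one
chance label–feature alignment, and no amount of round-averaging removes
that draw's bias, so re-permuting is what estimates the null mean.

## Planted-effect recovery metric

Ground truth stores, per planted effect, the windows fully contained in
its epoch.  Overlapping sliding windows (width 50, step 2) make
within-epoch features of one edge nearly collinear, so the
redundancy-eliminating RFE keeps only a few windows per effect and
legitimately selects boundary-straddling windows; a strict triple-level
Jaccard against the fully-contained set therefore understates recovery
(median ≈ 0.2–0.4 even when every effect is found).  The recovery metric
is computed at effect level: an effect counts recovered when some
selected triple matches its edge with a window overlapping its epoch, and
each selected edge matching no effect counts against the union.  Both
numbers are reported.

## Experiment sizes

Desk-scale validation uses N = 30 regions (33,060 DFC features),
40+40 subjects for recovery and DFC-vs-SFC cohorts (10 seeds each,
3 planted edges, |Δr| = 0.5, 70-timepoint epochs ≙ 11 contained windows),
20+20 for screening calibration (6 seeds), 40+40 for the permutation
null, 43+56 for the hold-out optimism demonstration (3 seeds), and
n = 43 patients (300-subject Monte-Carlo oracle) for clinical-coupling
recovery.  Subset-selection curves are evaluated to n_max = 60 with
5-fold inner CV; model evaluation uses 10–20 round repeated 10-fold CV.
These sizes make the whole validation run in a few minutes on one core
while keeping every planted quantity comfortably identifiable.

## Known limitations

- The generator's independence across regions (identity baseline) is
  optimistic; real connectomes have dense correlated backgrounds that
  would raise the screening floor and slow RFE.
- The ΔJ criterion holds α fixed when hypothetically removing a feature
  (the standard approximation); exact retraining per candidate would be
  quadratically more expensive.
- The AUC-vs-n curve is selection-biased by construction (see above);
  optimal_n should not be read as a generalization claim.
- With class imbalance the RBF SVM can collapse to majority-class
  prediction while still ranking well (SFC arm of the worked example:
  sensitivity 0 %, AUC 0.85) — accuracy-type metrics are unstable there,
  which is precisely why AUC drives subset selection.
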