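# Methods

## The model

A patient is represented by a bag of K tile-level feature vectors
f_1..f_K ∈ R^M (in a real deployment these come from a frozen feature
extractor applied to H&E whole-slide image tiles; here they are synthetic).
Attention-based multiple-instance pooling condenses the bag into one slide
feature

    z = Σ_k a_k f_k ,   a_k = softmax_k( wᵀ tanh(V f_kᵀ) ),

with trainable V ∈ R^{L×M}, w ∈ R^L.  A small fully connected head
(M → 128 → 64 → out, ReLU, dropout between layers) maps z either to

* **survival head** — 60 positive monthly hazard masses η_1..η_60
  (softplus output), parametrizing a piecewise-constant continuous-time
  hazard on a five-year monthly grid, or
* **binary head** — a single logistic output, the probability of death
  within five years.

The survival head is trained by the exact negative log-likelihood of the
piecewise-constant hazard model.  A follow-up time t maps to interval
k(t) = ⌈t⌉ and fraction ρ(t) = t − (k−1) (ρ = 1 at integer times; the
boundary convention is ours — the likelihood is continuous there, so the
choice only affects bookkeeping).  Follow-up beyond 60 months is
administratively censored at t = 60.  The binary head is trained with
binary cross-entropy weighted by inverse-probability-of-censoring weights:
Ĝ is the Kaplan–Meier estimator of the censoring distribution (censoring as
event, events leaving the risk set first at ties); a death at t ≤ 60 gets
weight 1/Ĝ(t⁻), a patient at risk at 60 months weight 1/Ĝ(60⁻), and a
patient censored earlier weight 0.  We evaluate Ĝ at the horizon as a left
limit so that the point mass of administrative censoring at exactly 60
months cannot down-weight the very group it defines; for continuous
censoring times this coincides with the usual right-continuous convention.
The BCE normalizes by the weight sum, keeping the loss scale comparable
across censoring regimes, and clips probabilities at 1e-12.

Survival curves follow as S(k) = exp(−Σ_{j≤k} η_j), and the **mortality
score** condenses a curve into one number,

    M = Σ_{k=1}^{60} H(k)  =  Σ_{j=1}^{60} (61−j) η_j ,

the cumulative hazard summed over the sixty monthly intervals.  Higher M,
steeper predicted decline.

## Training scheme

Frozen features, batch size 1, AdamW (decoupled weight decay on the weight
matrices; biases undecayed), linear learning-rate warmup over the first
fifth of the schedule then cosine annealing to zero, random tile
subsampling at train time (at least `min_tiles`, up to the whole bag;
validation and test always use all tiles), dropout between head layers, and
early stopping: the retained model is the epoch with the lowest validation
loss.  Five-fold cross-validation on the development cohort; the final
prediction averages the five fold models (pointwise mean of survival
curves, mean of binary probabilities).  A multi-extractor ensemble is
emulated by training members on independent random linear projections of
the tile features and averaging fold-averages.

Reference settings for a full-size cohort (thousands of patients,
M = 512): 100 epochs, warmup 20, peak rate 1e-5, weight decay 1e-6,
dropout 0.5, `min_tiles` 1000.  The synthetic experiments in this
repository run a proportionally scaled design — cohorts of 500 patients,
M = 32, 50–200 tiles per bag — and use a correspondingly scaled scheme:
40 epochs (warmup 8), peak rate 3e-4 (each fold sees roughly a tenth of
the optimizer steps, so the peak rate rises to keep the total travel
comparable), `min_tiles` 50 (so the subsampling augmentation still
engages), attention size L = 64, dropout 0.25, weight decay 0.3, and a
10× larger step on bias parameters.  The last three choices address two
small-cohort pathologies we observed: the output-layer biases must travel
far (from softplus(0) ≈ 0.69 per month down to realistic hazard levels
~0.01) while the weights need many small steps, and with few patients the
network memorizes bags quickly, so meaningful weight decay delays the
overfitting that early stopping reacts to.  All of these are exposed on
`TrainConfig`; the experiment configuration lives in
`milsurv.experiments.experiment_train_config`.

Gradients are computed by hand-written backpropagation through the
attention and head (the model is small enough that numpy suffices) and are
verified against central finite differences in the test suite.

## Recalibration

Cohort shift (scanner, site, case mix) moves the absolute level of the
predicted curves while typically preserving patient ranking.  Following
standard Cox-model recalibration: fit a proportional-hazards model on the
development cohort with the mortality score as the single covariate
(lifelines' Newton solver, Breslow ties), keep the score effect β̂, and
re-estimate the baseline cumulative hazard on the target cohort with the
Breslow estimator at fixed linear predictor β̂·M.  The recalibrated curve
is S(t|X) = exp(−Ĥ₀,new(t)·e^{β̂·M(X)}) on the monthly grid.  Ranking is
unchanged by construction (Spearman 1 before/after).  The baseline is
estimated on the whole target cohort — a best-case design; an honest
evaluation would split the target into calibration and test halves.

In a hazard-doubled world the identity S_recal = S_train² holds up to
Breslow noise and the curvature of the estimated cumulative baseline.  Our
check constructs the doubled world by halving all follow-up times (exact
hazard doubling for the constant baseline used there) so the Breslow
jumps cancel between numerator and denominator, and uses a well-specified
covariate (the log-scale latent risk) for the identity check; the raw
mortality score enters the Cox model linearly although the true log-hazard
is linear in log-score, and that deliberate misspecification (the score is
used raw, as in practice) would otherwise contaminate a machinery test
with model error.  The integrated-Brier improvement is checked with the
raw score.

## Risk strata and nested groups

UICC stage I–IIa defines the clinical low-risk stratum (CLR), IIb–IV the
high-risk stratum (CHR); missing stage excludes a patient.  Within a
stratum, nested risk groups come from a cross-validated threshold search:
for each validation fold every observed score except the ten lowest and
ten highest is tried as a cutoff and the two-group log-rank p-value is
recorded; the per-fold p-vs-threshold curves are linearly interpolated
onto a common grid (step 0.1 for mortality scores, 0.01 for probability
scores) over the intersection of fold ranges, averaged, and smoothed with
a discrete Gaussian kernel (σ = 1 grid step, truncated at 4σ, reflective
boundary); the cutoff is the grid point minimizing the smoothed curve,
smallest value on ties.  Patients at or below the cutoff are "lower-risk".
The search is deterministic given the fold data.  The achieved smoothed
p-value is always reported alongside the cutoff — in low-event strata no
threshold may reach significance, and that is a result, not an error.

## Evaluation

* Harrell's C (binary/score models): concordant fraction of comparable
  pairs, prediction ties 0.5, standard censoring admissibility.
* Time-dependent C (survival curves, Antolini): pairs compared through
  S_i(t_i) at the earlier event time; curves are monthly steps, S(t) for
  t ∈ (k−1, k] is the value at month k.
* Brier score at 60 months and integrated Brier score: Graf IPCW weighting
  with the same Ĝ conventions as training; IBS integrates BS(t) on months
  1..60 by the trapezoid rule divided by the 59-month span.  A
  complete-case variant of the Brier score is available.
* 95% CIs: percentile bootstrap over patients, 1000 replicates by default
  (200 in the analysis scripts for runtime); resamples on which a metric is
  undefined are redrawn and counted.
* Both pairwise metrics are O(n²) vectorized and are tested against
  brute-force pair enumeration; the log-rank statistic is tested against a
  textbook risk-set computation and lifelines.

Clinical and combined Cox models: one-hot encoded age group and T stage
(plus N and M for CHR), lowest level as reference, MX imputed to M0,
complete cases only, ridge penalizer 0.1 (l1_ratio 0) via lifelines
(Breslow ties); the combined model adds the (recalibrated) mortality score
as a continuous covariate, unstandardized.  Constant design columns within
a stratum are dropped with a warning rather than raised — they carry no
information and routinely appear in small strata.  Survival predictions
use our Breslow baseline at the fitted coefficients.

## Synthetic cohorts

Each patient has a latent risk r ~ N(0,1) that drives everything:

* **Features**: K ~ U{K_min..K_max} tiles of N(0, I_d) noise; a fraction
  (default 0.2) are informative and shifted by `signal_strength`·r along
  the first canonical axis.  The fixed direction makes attention recovery
  testable.  Real tile features are not Gaussian and their informative
  structure is unknown; passing tests show the pipeline recovers planted
  signal of this simple geometry, not that it works on histology.
* **Survival**: piecewise-constant hazard h(t|r) = h₀(k)·e^{β·r} on the
  monthly grid (default h₀ ≡ 0.006/month, β = 1, giving a ~30% five-year
  event fraction, in the range of a resected CRC development cohort), the
  last month's hazard carried forward beyond 60 months; times drawn by
  analytic inversion of a unit exponential.  Random censoring is
  exponential with its rate calibrated by bisection against the
  closed-form censoring probability (Gauss–Hermite over r) to hit a target
  fraction censored before 60 months (default 0.1).  Administrative
  censoring at 60 months is an explicit separate step.
* **Staging**: a monotone map from the latent-risk quantile to T/N/M/UICC
  (about 20% I, 20% IIa, 10% IIb, 30% III, 20% IV), so CHR is enriched for
  high risk as staging is for real tumours; age group is drawn
  independently.  The deterministic link makes the stage carry coarse risk
  information, leaving headroom the image score can add — the regime the
  combined model targets.
* **Cohort shift**: baseline-hazard scaling (event times redrawn from the
  same latent risks on an independent substream), an affine transform of
  all tile features, and optionally a different censoring rate.  A pure
  feature shift leaves the survival records bitwise unchanged.
* Every patient has an independent substream seeded by (cohort seed,
  patient index, stream), so enlarging a cohort preserves existing
  patients.

## Numerical choices and degenerate inputs

Softplus keeps hazards positive; its saturation is handled with the
log1p(exp(−|x|)) form.  The binary risk is clipped to [1e-12, 1−1e-12] so
the open-interval contract survives float saturation.  Constant mortality
scores yield β = 0 (flagged, not an error).  A fold with ≤ 21 patients has
no admissible thresholds and raises.  All-censored cohorts raise for IPCW
weights and for the log-rank test; the Kaplan–Meier estimator returns the
flat curve.  Ties: events precede censorings at equal times everywhere.

## Problem sizes used in the shipped experiments

End-to-end signal recovery: training cohorts of 500 (five folds), test
cohorts of 200, ten cohort seeds plus ten zero-signal controls.
Recalibration: cohorts of 6000 (Breslow curvature falls with n; at this
size the identity holds to ~1.5% on the monthly grid).  Threshold
recovery: five folds of 200 patients, twenty seeds.  Model-comparison
analysis: one development cohort of 400 and two shifted cohorts of 400.
The oracle time-dependent C-index of the generating model on a 200-patient
test cohort varies between roughly 0.69 and 0.79 across seeds — a useful
reminder that a single small test cohort bounds what any fitted model can
show.

## Known limitations

The generator's Gaussian tile features and single informative direction
are a deliberate simplification; nothing here validates feature extractors
or tissue segmentation.  The scaled training scheme was designed for the
synthetic cohort size and is not a recommendation for full-size data,
where the reference settings apply.  Recalibration uses the whole target
cohort.  The CV-ensemble's predictions on its own development cohort are
optimistic (each patient is seen by four of five fold models at train
time); external-cohort numbers are the honest ones.
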