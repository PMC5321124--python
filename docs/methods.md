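# Methods

`itersurv` predicts exact survival times for right-censored cohorts by
turning the censored-regression problem into a complete-data regression
problem: censored outcomes are multiply imputed, an ensemble of regression
models is trained on the completed log times, and the imputation and the
model iteratively inform each other.

## The model

Let (Y_i, Δ_i) be the observed follow-up time (days) and event indicator
(Δ_i = 1: death observed; Δ_i = 0: right-censored), and X_i the covariate
vector of subject i.

**Step I — covariate-free initial imputation.** Every censored subject
receives an exponential tail: Y_i^new = Y_i + E_i with
E_i ~ Exp(scale α_study). The scales are per-study tuning parameters in
days; the shipped defaults are 400 / 420 / 460 for the three training
studies the method was developed on, with 420 for any other study label.
Observed deaths are never modified — this conservation law holds at every
stage of the engine.

**Step II — iterate model fit and adjustment.** Each iteration
(a) selects features: a regularized random forest (mtry 2, coefReg 0.95),
an RBF-kernel SVR and a two-component PLS regression are fit to the
completed log times; each model's variable importances are min–max scaled
to [0, 100], averaged, and features with mean importance above γ (default
24) are kept; (b) fits the M = 5 prediction models (regularized random
forest, RBF-SVR, quantile regression forest, polynomial SVR, PLS) on the
reduced design and produces **out-of-fold** predictions through the
dataset-level fold index, so a subject's imputed value never depends on a
model that saw its own outcome; (c) adjusts: for each censored subject the
per-model log predictions are averaged (a geometric mean in days — all
models operate on log time); a prediction above the censoring time is
accepted as the new completed value, otherwise the subject is re-imputed
as Y_i + E*, E* ~ Exp(scale α*, default 80 days). Completed times
therefore always exceed the censoring time strictly. Iteration stops when
the cross-validated iAUC of the averaged predictions improves by less than
a threshold (default 0.2, deliberately coarse to avoid over-fitting) or at
the iteration cap.

**Step III — stacking.** Per covariate-imputation stream m = 1..I, the
five prediction models are refit per fold on the final completed outcomes
(tuned "final"-stage hyperparameters), giving out-of-fold log predictions.
These are averaged over the I streams per model, and a LASSO with the log
completed time as outcome learns the combination weights (intercept
included, members not re-standardized, coefficients unconstrained; the
penalty is chosen by internal 10-fold CV unless fixed). A new subject's
prediction is exp(intercept + w·z̄) where z̄ is the stream-averaged member
log-prediction vector. With I > 1 the per-stream completed outcomes are
not pooled during iteration; the stacking target is the per-subject mean
of the log completed times across streams (observed subjects unchanged).

## Covariate completion and transformation

Missing covariates are completed by chained equations: each incomplete
column is regressed on all other covariates plus log follow-up time and
the event indicator (including the outcome among the predictors is
standard multiple-imputation practice and the package default).
Continuous targets use predictive mean matching with 5 donors — the
imputed value is copied from an observed donor whose fitted mean is
nearest, so imputations always lie in the observed range; categorical
targets sample a level from a multinomial-logistic fit. The procedure is
repeated I times (default 5) with distinct seeds; observed cells are never
altered. Completed covariates are one-hot encoded with the full indicator
set (importance stays attributable per level; the learners tolerate the
collinearity), Box-Cox transformed with power 0.2 (columns with values
≤ 0 are first shifted by 1 − min) and standardized with parameters fitted
on training rows.

## Evaluation metrics

`td_auc` is the cumulative/dynamic time-dependent AUC with inverse
probability-of-censoring weights from the Kaplan-Meier estimate of the
censoring distribution; score ties count 1/2, and horizons with no case
or no control are excluded. `iauc` integrates AUC(t) over the observed
event times up to τ (default the 90th percentile of follow-up), weighted
by the KM-estimated event-time mass; it lies in [0, 1], equals the
constant when AUC(t) is constant, and is invariant to strictly monotone
transforms of the scores. `rmse_uncensored` scores predicted days against
observed days over subjects with Δ = 1 only. Cross-validated metrics are
pooled over held-out folds, not fold-averaged; per-fold values are kept
for diagnostics.

## Risk-set imputation comparator

Risk-set imputation replaces each censored time by a uniform draw from
the event-like completed times strictly beyond it. Censored times are
processed **largest-first** so a later-censored subject's imputed value is
available to earlier-censored ones; this is the redistribute-to-the-right
construction, and exact small-case enumeration shows it is the order under
which the mean imputed-data survival curve reproduces the Kaplan-Meier
estimate (smallest-first processing provably biases the imputed curve low
in the tail). A subject censored beyond the last event-like time keeps its
censoring time plus an Exp(α*) tail and is flagged.

## Survival-forest benchmark

The benchmark forest grows B bootstrap trees (default 1000; desk-scale
runs use 200). At each node, up to 10 random cut points per candidate
feature (mtry = ⌈√p⌉ by default; random level bipartitions for features
flagged categorical, counted against the same budget) are scored by the
standardized two-sample log-rank statistic |O − E|/√V accumulated over
distinct event times with hypergeometric variance; children must hold at
least 15 subjects and one event. Leaves carry Nelson-Aalen cumulative
hazards of their in-bag members on the grid of training event times;
ensemble survival is exp(−mean CHF), and the exact-time prediction is the
smallest grid time where the curve falls to 1 − q/100, with q common to
all subjects (shipped default 37; tunable by CV to minimize RMSE on
uncensored subjects, ties toward smaller q). Curves that never cross
return the largest grid time and are flagged — auditability was preferred
over extrapolation.

## Synthetic cohorts

The generator emulates the structure of a multi-trial metastatic
prostate-cancer cohort. Defaults: three studies of 300 subjects with
small baseline shifts (±0.05 on log time); log T = intercept + X·β + σ·ε
with ε standard normal (log-normal AFT — chosen because all learners model
log time; all four trials' survival curves are similar so the shifts are
mild); intercept log(550) days (median survival ≈ 18 months, typical of
docetaxel-treated mCRPC); four informative continuous covariates with
β = (0.5, −0.4, 0.3, −0.25) out of eight, two 3-level categoricals with
small ordered contrasts; σ = 0.55, which yields a cross-validated iAUC
near 0.9 on the defaults — an optimistic but recognizable signal level.
Censoring: 65% of subjects draw a censoring time uniform in the 6–20-month
window (183–609 days) — concentrating censoring mid-follow-up as in the
motivating trials — and the rest are followed to an administrative horizon
of 2500 days; overall censoring lands near 40%. Dependent censoring
multiplies the window draw by exp(X·γ) (default γ = 0.5 on the strongest
survival covariate), so short-lived subjects are censored earlier; at
n = 5000 the naive KM median visibly overestimates the true median — the
scenario that motivates covariate-guided imputation. Study-block
missingness masks chosen features per study with stated probabilities.
What the generator does not emulate: the real trials' covariate
distributions and consolidation, informative visit schedules, and
non-log-normal hazards (a Weibull option is deliberately out of scope).
Tests passing on these cohorts demonstrate the mechanics and the
distributional identities, not clinical transportability.

## Desk-scale choices and numerical conventions

End-to-end checks run cohorts of n = 400–500 with 6 covariates, a single
covariate-imputation stream (no missingness in those cohorts), 3 folds,
iteration cap 2, 25–50-tree regularized forests and 100-tree quantile
forests; the survival-forest benchmark uses B = 200. Scaling down trades
variance for runtime without changing any algorithmic path. Other
conventions: risk scores passed to the AUC are negated predicted days;
fold assignment is a shuffled round-robin (exact balance — the stricter
reading of an "even" split), with i.i.d. assignment as an option;
zero-variance columns standardize to zero; an empty feature selection
falls back to the top max(5, √p) features with a warning; selection ties
break by mean importance descending then feature name; kernel widths map
the original toolchain's σ to the RBF coefficient and the polynomial
"scale" to the kernel coefficient with offset 1; the quantile forest
predicts the median (the ensemble-feeding quantile is otherwise
unspecified); all randomness descends from a single seed per run and
reruns are bit-identical.

## Known limitations

- The exponential scales α, α* are tuned by cross-validated iAUC, a
  rank-based criterion invariant to monotone transforms of predictions.
  They therefore cannot calibrate the *location* of imputed times. On
  cohorts whose mean residual life after censoring is far from α (the
  dependent-censoring defaults here: ≈ 700 days vs α ≈ 420), the
  completed outcomes for censored subjects are systematically low, and
  every downstream model inherits that bias even when its ranking is
  nearly perfect. Under such conditions the iterative adjustment does not
  reliably reduce oracle RMSE on censored subjects' true times relative
  to a model trained on step-I imputations alone — discrimination
  improves, day-scale calibration does not.
- Under dependent censoring the censoring time itself carries covariate
  information, so the "covariate-free" baseline C + Exp(α) is a stronger
  predictor of the remaining lifetime than its name suggests.
- Averaging member predictions on the log scale yields day-scale medians,
  not means; on right-skewed survival distributions this is a further
  source of downward bias for long survivors.
- PMM cannot extrapolate beyond the observed range of a column; block
  missingness that truncates a covariate's support is imputed
  conservatively.
- The forest benchmark caps predictions at the largest training event
  time; true times beyond follow-up are unreachable by construction.
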