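# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limits of what the test suite demonstrates.

## Data model and curation

The unit of analysis is one patient's weekly PHQ-9 series over weeks 0–6.
Week 0 is the single pre-treatment score; week w ≥ 1 is the arithmetic
mean of daily scores with day index in the half-open window [7(w−1), 7w)
counted from the first treatment day.  Patients who stop early have their
final observed week carried forward (LOCF) and those weeks flagged.
Interior gaps — a missing week with observed data on both sides — are not
covered by a trailing-LOCF rule, so the package fills them by linear
interpolation between the flanking weeks and flags them; this is a
documented choice, not an established convention.  Patients lacking week 0
or lacking any post-baseline week are excluded.  Responder status (the
"50% rule") is computed on raw scores only: (week0 − week6)/week0 ≥ 0.5,
inclusive, with a zero baseline defined as non-response.

## Latent class mixed model

The LCMM is a K-component mixture (K = 1..5) of linear mixed models with
class-specific polynomial mean curves of degree d ∈ {1, 2, 3} on the week
scale, a patient-level random intercept with variance τ² shared across
classes, and residual variance σ².  The marginal covariance per patient is
τ²J + σ²I, whose two-eigenvalue structure (σ² + Tτ² on the constant
vector, σ² elsewhere) gives closed forms for densities, GLS updates and
BLUPs.

*Estimation.*  EM with exact M-steps: class proportions are posterior
column means; class coefficients are GLS fits of the posterior-weighted
mean profiles; the variance pair (τ², σ²) has a closed-form update from
the two quadratic summaries of the weighted residuals, with τ² truncated
at 0 when the unconstrained update crosses the boundary.  Each M-step
maximizes the expected complete-data log-likelihood, so the observed-data
log-likelihood is non-decreasing across iterations.  Convergence is a
relative log-likelihood change below 1e−8; the iteration cap is 2000
because overfitted class counts (fitting K = 3 to 2-class data) approach
their optimum in long plateaus.

*Multi-start.*  Mixture likelihoods are multimodal.  The default 20 starts
comprise one k-means partition of the score vectors plus seeded
perturbations that reassign a random quarter of patients.  A converged
start always beats a non-converged one; ties go to the best
log-likelihood.

*Identifiability conventions.*  Classes are re-ordered after fitting by
fitted week-6 mean change, most improvement first, so "class 0" is always
the improvement trajectory and label switching cannot break comparisons
across folds.  Posterior ties in modal assignment go to the
better-improving class.

*Baseline-corrected variant.*  When modeling differences from baseline the
week-0 column is identically zero and is dropped from the likelihood;
keeping it would drive σ̂² toward a degenerate boundary.  Posteriors for a
partially observed patient use only the weeks that enter the fit's
likelihood, returning the prior when none are available.

*Information criteria.*  BIC = −2ℓ + p ln n and SABIC = −2ℓ +
p ln((n+2)/24), with n the number of subjects and p = (K−1) + K(d+1) + 2.

## Exponential-decay NLME

The mean model is Change·exp(−t/B) + End.  The exponent is parameterized
as −t/B with B a time constant in weeks — the natural reading of a decay
"rate" whose fitted value is near two weeks.  B is handled on the log
scale internally so the time constant stays positive; the random-effect
covariance Ψ is therefore expressed on the (Change, log B, End) scale.

*Estimation.*  Alternating, Lindstrom–Bates style.  (a) Penalized
nonlinear least squares for all patients' random-effect modes at once — a
damped Gauss–Newton with per-patient Levenberg damping, vectorized across
the cohort with batched 3×3 solves.  (b) One EM sweep of fixed-effect and
variance updates on the model linearized at the current modes.  The
proposal from (b) is accepted under step-halving against the
Laplace-approximate marginal log-likelihood, which keeps the outer
iteration monotone even when the linearization overshoots (without this,
the iteration oscillates on data that do not follow a decay curve).  Two
further safeguards: the fixed-effect solve uses least squares with log-B
clipped to [−3, 4], because when B grows large exp(−t/B) becomes collinear
with the intercept; and variance components that collapse toward zero are
pinned at a small floor (1e−8 of the data variance), since EM approaches a
variance boundary at an asymptotically slow crawl.

*Model comparison.*  Nested random-effect structures are compared by
LRT = 2(ℓ_full − ℓ_reduced) with df the difference in parameter counts
(full: 3 fixed + 6 covariance + 1 residual = 10; reduced without the B
effect: 7), plus AIC/BIC deltas.  The LRT null here is a boundary case
whose true distribution is a chi-square mixture; the test is used as a
model-preference heuristic, not an exact size-α test.

## Forecasting from weeks 0..w

*LCMM path.*  Posterior class probabilities are computed from the observed
weeks; the forecast at every week is the posterior-weighted average of
class mean curves plus the posterior-weighted empirical-Bayes random
intercept (BLUP τ²1ᵀV⁻¹(y − Xβ_k) over the observed weeks).  For
baseline-corrected fits the forecast is re-anchored at the observed week-0
score.  The BLUP is recomputed for each w — the only option for patients
held out of the training fit.

*Decay path.*  With B fixed at the training population estimate, each
observed week t ≥ 1 yields End_t = [y(t) − y(0)e^(−t/B)] / (1 − e^(−t/B)).
When several weeks are observed these are combined with weights
(1 − e^(−t/B))², which is the weighted-least-squares (and, under the
model, maximum-likelihood) solution for End given fixed B and
Change = y(0) − End; it reduces to the single-week formula when only one
post-baseline week exists.  At w = 0 the forecast falls back to the
training population End — with a typical training cohort this predicts
nearly everyone to the same side, reproducing the degenerate
sensitivity/specificity pattern a baseline-only forecast shows.  Predicted
trajectories re-enter the decay curve and are anchored at the observed
baseline, so predicted responder calls always divide by the observed
week-0 score.  Decay forecasts can additionally be assigned a trajectory
class by scoring the predicted 7-week curve under a latent-class fit
trained on the same folds.

## Evaluation

Folds are stratified: within each label stratum patients are shuffled and
dealt round-robin with the fold counter running across strata, so fold
sizes differ by at most one and label proportions are preserved to within
one patient.  Strata smaller than k are dealt the same way and noted.
Model-selection folds use a single stratum (plain randomization);
prediction-experiment folds stratify on the reference trajectory classes.

AUC of a dichotomous prediction is the ROC area of the two-level score,
which equals (sensitivity + specificity)/2 — balanced accuracy.  No
continuous score is invented for binary calls.  Confidence intervals for
classification metrics are percentile 95% intervals over 2000 bootstrap
replicates resampled within observed-label strata; Pearson correlations
pool all patient-week pairs in a fold and use Fisher-z intervals.  All
metrics are computed per fold and then averaged, including the CI bounds.

The improvement-class response definition takes its ground truth from a
reference latent-class fit of the *full* cohort, mirroring the standard
workflow; the mild train/test leakage this implies is inherent to that
design and documented rather than "fixed".

Model selection over the candidate grid reports fold-averaged BIC, SABIC,
held-out predicted-versus-observed correlation, and minimum modal-class
share.  Delta columns subtract the more complex model's criterion from the
less complex one's (positive favors complexity), between adjacent
polynomial orders within class count and adjacent class counts within
order.  Configurations whose smallest class holds under 5% of the sample
are flagged; a flat-trajectory indicator (some class improving by fewer
than 2.5 points at week 6) is printed as information.  The automatic
choice is the best-BIC unflagged configuration; qualitative judgment
(interpretability, known-truth constraints) is deliberately left to the
user.

## Covariate analysis

Class membership weights are each patient's modal-class posterior
probability.  Patients who switched coil (or protocol) are excluded from
the corresponding analysis, and coil and protocol are never entered in the
same model.  SMOTE balances classes by interpolating numeric features
between a minority point and one of its five nearest minority neighbors
(distances on standardized numerics) at a uniform random fraction;
categorical attributes and the membership weight are copied from the seed
point; singleton classes are duplicated with a warning.  The multinomial
logistic log-likelihood is weight-multiplied and maximized with L-BFGS and
an analytic gradient; the largest class is the reference; BIC uses
n = the sum of weights.  Runaway coefficients (perfect separation) trigger
a ridge-stabilized refit with a warning.  Forward selection adds, at each
step, the candidate with the largest BIC reduction, and stops when no
candidate reduces BIC by more than 5.

## Synthetic-data generator

The generator is the package's test bed and parameter-recovery oracle.

*Latent-class cohort.*  Class ~ Categorical(π), patient intercept shift ~
N(0, τ²), score(t) = class polynomial(t) + shift + N(0, σ²) at every week
including week 0, clipped to [0, 27] after noise (the instrument is
bounded; the models are not; the clipped fraction is reported and stays
under 5% at the defaults).  Defaults emulate the published registry
cohort: π = (0.4076, 0.5924); intercept 17.86 with τ = 4.56, matching the
baseline distribution; cubic change curves solved so the week-6 mean
changes are exactly −6.87 (improvement; early-steep) and −2.05
(non-response; near-flat).  The residual SD default is σ = 1.0, the
standard error of a weekly mean of about five daily ratings with a
day-to-day within-patient SD near 2.2 points.

*Decay cohort.*  (Change_i, log B_i, End_i) = population + multivariate
normal deviation with covariance Ψ; B is lognormal because a time constant
must be positive (with a 0.1-week guard).  Defaults: population
(12, 2.11, 6), diagonal Ψ with SDs (3.0, 0.25, 2.0), residual σ = 1.5,
n = 240.

*Dropout.*  Each patient is independently truncated after a uniformly
chosen last observed week in 1..5 with a configurable probability
(default 4%, a handful of patients per cohort), feeding the LOCF path.

*What the generator does not emulate.*  Random effects in the
latent-class generator are intercept-only, so within-class week-6 change
varies only through measurement noise (SD ≈ 1.4 points), far less than
the 2.5–6 point within-class spreads reported for real cohorts.  Two
consequences: the synthetic 50%-responder rate (~6%) is below registry
rates (~18%), and the 50%-reduction definition remains hard to predict at
every w because the model has no patient-specific slope information to
recover.  Covariates are generated independently of class unless an
association is explicitly planted, so covariate-analysis tests check
procedure behavior (false/true selection rates), not effect sizes.
Passing tests therefore demonstrate correctness of the machinery and
calibration under the stated generating structure — not that real rTMS
trajectories follow these models.

## Numerical and testing choices

Problem sizes in the test suite and acceptance script are chosen to keep a
laptop run comfortable: cohorts of 240 patients, 50 replicates for
selection-rate checks, 100 replicates for decay-parameter recovery, 500
simulation runs for bootstrap-coverage calibration.  Likelihood code is
cross-checked against independent oracles — Gauss–Hermite quadrature over
the random intercept for the mixture likelihood, adaptive quadrature for
the Laplace approximation (exact for a linear random effect), brute-force
multivariate-normal densities for posteriors and BLUPs.  All randomness
flows from explicit integer seeds; pipeline stages derive their streams
from one master seed.

## Known limitations

- Intercept-only random effects in the LCMM (a random slope is a config
  option for the generator but not the estimator); no class-specific
  residual variances; no covariates in the trajectory or membership
  submodels.
- The decay model fixes B at the population level at forecast time; no
  per-patient B estimation for held-out patients.
- The LRT for random-effect structures ignores the boundary-null issue.
- SMOTE's handling of mixed-type features (copy categoricals from the
  seed point) is one of several published conventions.
- Interior-gap interpolation is a pragmatic rule for data the trailing
  LOCF rule does not cover.
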