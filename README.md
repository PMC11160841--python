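# tmstraj

Trajectory modeling and early response prediction for repetitive
transcranial magnetic stimulation (rTMS) courses in treatment-resistant
depression.

Clinicians treating depression with rTMS face a practical question: after
one, two, or three weeks of a six-week course, can weekly symptom scores
already tell whether a patient will respond?  `tmstraj` is a research
library for answering that question with weekly PHQ-9 scores (range 0–27).
It is aimed at biostatisticians and computational psychiatrists working
with naturalistic registry-style data.

## Models

Two complementary trajectory models are implemented from scratch, with
everything needed to evaluate them honestly under cross-validation.

**Latent class mixed model (LCMM).**  Patient *i* belongs to an unobserved
class *k* with probability π<sub>k</sub>; within class *k* the vector of
weekly scores over weeks 0–6 is

> y<sub>i</sub> | k ~ N(Xβ<sub>k</sub>, τ²J + σ²I)

with X a polynomial design on the week index (degree 1–3), a patient-level
random intercept of variance τ², and residual variance σ².  Fitting is by
multi-start EM with closed-form M-steps; the package reports posterior
class membership, BIC, and the sample-size-adjusted BIC (SABIC, penalty
ln((n+2)/24)).  Models can be fit to raw scores or to differences from the
week-0 baseline.

**Exponential-decay nonlinear mixed model (NLME).**  Each patient's score
follows

> y<sub>it</sub> = Change<sub>i</sub> · e<sup>−t/B<sub>i</sub></sup> + End<sub>i</sub> + ε<sub>it</sub>

a total modeled reduction that decays with time constant B (weeks) toward
an asymptotic end score.  Any subset of the three parameters can carry
patient-level random effects (B on the log scale); estimation alternates
penalized nonlinear least squares with linearized mixed-model updates,
Lindstrom–Bates style, and reports a Laplace-approximate marginal
likelihood.

**Forecasting.**  Given only weeks 0..w of a held-out patient, the LCMM
path combines class mean curves weighted by the patient's posterior class
probabilities plus an empirical-Bayes intercept; the decay path solves the
rearranged decay curve for End with B fixed at the training population
value and re-enters it into the curve.  Forecasts feed sensitivity /
specificity / AUC (with stratified-bootstrap CIs) for two response
definitions — a ≥50% score reduction at week 6, and membership in the
improvement trajectory — plus Pearson correlations of predicted versus
observed scores.

Because registry data of this kind are not publicly deposited, the package
ships a first-class synthetic-data module whose defaults emulate the
published cohort structure: a 40.8/59.2 improvement/non-response split,
baseline PHQ-9 ≈ N(17.86, 4.56²), class mean week-6 changes of −6.87 and
−2.05 points, and early-termination missingness repaired by
last-observation-carried-forward.

## Worked example

```python
from tmstraj.lcmm import LcmmConfig, fit
from tmstraj.simulate import LcmmSimSpec, simulate_lcmm_cohort

cohort, labels, _ = simulate_lcmm_cohort(LcmmSimSpec(n_patients=238, seed=3))
result = fit(cohort, LcmmConfig(n_classes=2, degree=3,
                                baseline_corrected=True, n_starts=10, seed=0))
print(result.pi, result.week6_change())
```

prints (see `examples/02_fit_latent_classes.py`)

```
class proportions: [0.398 0.602]
fitted week-6 mean change per class: [-7.2  -2.29]
modal-class agreement with generating labels: 97.5%
```

— the fit recovers the generating 41/59 class split and the −6.9 / −2.1
point mean improvements, and assigns 97.5% of patients to their true
trajectory.  The `examples/` directory walks through every capability:
simulation and curation, both model fits, partial-data forecasting,
cross-validated model selection and prediction (the week-by-week AUC
table), and the SMOTE-balanced covariate analysis.

A thin CLI ties the stages into a reproducible pipeline driven by one YAML
config and master seed:

```bash
tmstraj all --config run.yaml
```

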