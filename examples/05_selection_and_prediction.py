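"""Cross-validated model selection and week-by-week predictive power.

First a small candidate grid of latent-class models is compared by
fold-averaged BIC/SABIC, test-set correlation and minimum class share.
Then the prediction experiment trains on complete courses and forecasts
held-out patients from an increasing number of weeks, reporting
sensitivity, specificity and AUC for the 50%-reduction response definition.
"""

from tmstraj.evaluate import prediction_experiment, select_lcmm
from tmstraj.simulate import LcmmSimSpec, simulate_lcmm_cohort

cohort, _, _ = simulate_lcmm_cohort(LcmmSimSpec(n_patients=238, seed=6))

table, chosen = select_lcmm(
    cohort, n_classes_grid=(1, 2, 3), degree_grid=(2, 3), modes=(True,),
    seed=0, n_starts=4,
)
cols = ["degree", "n_classes", "bic", "sabic", "test_r", "min_class_share"]
print(table[cols].round(2).to_string(index=False))
print(f"best unflagged BIC: {chosen['n_classes']} classes, degree {chosen['degree']}\n")

report = prediction_experiment(cohort, "lcmm-bc", seed=1, n_boot=500, n_starts=6)
for rd in ("improvement_class", "fifty_percent"):
    sub = report.rows[report.rows.response_def == rd]
    print(f"response = {rd}")
    print(sub[["w", "sensitivity", "specificity", "auc", "r"]].round(3)
          .to_string(index=False))
# Improvement-trajectory membership becomes predictable within a few weeks
# (AUC near 1 by mid-course).  The strict 50%-reduction rule is harder: with
# intercept-only patient effects few patients sit above the threshold, the
# model is biased toward predicting non-response (high specificity, low
# sensitivity), and AUC rises more slowly.
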