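"""Forecast a held-out patient's course from only the first two weeks.

Both prediction paths are shown: the latent-class forecast (posterior-
weighted class curves plus an empirical-Bayes intercept) and the decay
forecast (end score solved from the rearranged decay curve with the
population time constant, then re-entered into the curve).
"""

import numpy as np

from tmstraj.decay import fit_nlme
from tmstraj.forecast import decay_forecast, lcmm_forecast
from tmstraj.lcmm import LcmmConfig, fit
from tmstraj.simulate import DecaySimSpec, simulate_decay_cohort

cohort, truth, _ = simulate_decay_cohort(DecaySimSpec(seed=5))
train, test_patient = cohort[:-1], cohort[-1]

lcmm_fit = fit(train, LcmmConfig(2, 3, baseline_corrected=True, n_starts=8, seed=0))
decay_fit = fit_nlme(train)

w = 2
fc_l = lcmm_forecast(lcmm_fit, test_patient, w)
fc_d = decay_forecast(test_patient, w, decay_fit.params.b,
                      end_fallback=decay_fit.params.end)

print(f"observed weeks 0..6:      {np.round(test_patient.weekly_scores, 2)}")
print(f"latent-class forecast:    {np.round(fc_l.predicted, 2)}"
      f"   class posterior {np.round(fc_l.class_posterior, 3)}")
print(f"decay forecast:           {np.round(fc_d.predicted, 2)}"
      f"   predicted end score {fc_d.predicted_end:.2f}")
print(f"predicted responder (50% rule): latent-class {fc_l.predicted_responder}, "
      f"decay {fc_d.predicted_responder}")
# Weeks 0..2 informed the forecasts; weeks 3..6 are model extrapolations.
# Both paths anchor at the observed baseline score.
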