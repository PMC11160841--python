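import numpy as np
import pytest

from tmstraj.simulate import (
    DecaySimSpec,
    LcmmSimSpec,
    simulate_decay_cohort,
    simulate_lcmm_cohort,
)


@pytest.fixture(scope="session")
def lcmm_cohort():
    """Default two-class cohort (n=240) with generating labels."""
    cohort, labels, info = simulate_lcmm_cohort(LcmmSimSpec(n_patients=240, seed=101))
    return cohort, labels, info


@pytest.fixture(scope="session")
def decay_cohort():
    """Default exponential-decay cohort (n=240) with per-patient truth."""
    cohort, truth, info = simulate_decay_cohort(DecaySimSpec(seed=202))
    return cohort, truth, info


@pytest.fixture(scope="session")
def lcmm_fit_default(lcmm_cohort):
    """Baseline-corrected two-class cubic fit of the default cohort."""
    from tmstraj.lcmm import LcmmConfig, fit

    cohort, _, _ = lcmm_cohort
    return fit(
        cohort,
        LcmmConfig(n_classes=2, degree=3, baseline_corrected=True, n_starts=8, seed=7),
    )


@pytest.fixture(scope="session")
def decay_fit_default(decay_cohort):
    from tmstraj.decay import fit_nlme

    cohort, _, _ = decay_cohort
    return fit_nlme(cohort)


def make_series(scores, pid="P0", **kw):
    from tmstraj.curation import PatientSeries

    return PatientSeries(patient_id=pid, weekly_scores=np.asarray(scores, float), **kw)
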