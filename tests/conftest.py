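import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from t1dcea.cohort import PatientProfile, default_imss_spec, generate_cohort
from t1dcea.disease import (
    ComplicationDef, DiseaseParams, MortalityTable, default_disease_params,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_patient(
    pid=0, sex="female", age=32.3, duration=18.5, hba1c=9.2,
    complications=(), medications=(), severe_hypo_rate=22.4,
) -> PatientProfile:
    """A hand-built patient with IMSS-mean biomarkers."""
    return PatientProfile(
        id=pid, sex=sex, age=age, diabetes_duration=duration, hba1c=hba1c,
        bmi=25.1, sbp=107.0, total_cholesterol=179.7, hdl_cholesterol=51.9,
        ldl_cholesterol=100.9, triglycerides=145.7, egfr=58.1,
        smoker=False, drinker=False,
        complications=frozenset(complications),
        medications=frozenset(medications),
        severe_hypo_rate=severe_hypo_rate,
    )


def uniform_cohort(n, **kw):
    return [make_patient(pid=i, **kw) for i in range(n)]


def single_complication_params(
    name="angina", prob=0.2, fatality=0.0, mortality=None, rr=1.0,
) -> DiseaseParams:
    """Two-state toy: one complication with constant per-cycle probability."""
    hazard = float("inf") if prob >= 1.0 else -float(np.log(1.0 - prob))
    return DiseaseParams(
        reference_hba1c=9.2,
        complications=[
            ComplicationDef(
                name=name, baseline_annual_hazard=hazard,
                rr_per_pct_hba1c=rr, fatality_prob=fatality,
            )
        ],
        background_mortality=mortality or MortalityTable.zero(),
    )


@pytest.fixture(scope="session")
def imss_cohort_small():
    return generate_cohort(default_imss_spec(n=150, seed=11))


@pytest.fixture(scope="session")
def disease_params():
    return default_disease_params()
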