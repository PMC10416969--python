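import pytest
from hypothesis import HealthCheck, settings

import cgmcal as c

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def small_cohort():
    """Default error model with noise; 3 patients x 7 days (~126 readings)."""
    return c.generate_cohort(c.CohortConfig(n_patients=3, duration_days=7, seed=42))


@pytest.fixture(scope="session")
def medium_cohort():
    """Default study conditions (9 patients x 14 days, ~756 readings)."""
    return c.generate_cohort(c.CohortConfig(seed=42))


@pytest.fixture(scope="session")
def constant_error_cohort():
    """Noiseless sensor whose error is exactly +15 mg/dL everywhere."""
    em = c.ErrorModelSpec(
        per_cluster_bias=(15.0,) * 6,
        per_cluster_slope=(0.0,) * 6,
        covariate_coefficients=(0.0,) * 7,
        noise_sd=0.0,
        patient_offset_sd=0.0,
    )
    return c.generate_cohort(
        c.CohortConfig(n_patients=3, duration_days=7, seed=5, error_model=em)
    )


@pytest.fixture(scope="session")
def linear_noiseless_cohort():
    """~1000 readings with the default cluster-bias + covariate-slope error
    mechanism but zero noise and zero patient offset (exact recovery)."""
    em = c.ErrorModelSpec(noise_sd=0.0, patient_offset_sd=0.0)
    return c.generate_cohort(
        c.CohortConfig(seed=11, references_per_day=8, error_model=em)
    )
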