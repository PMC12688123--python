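import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def small_m7_cohort():
    """One Study-3 cohort simulated from M7 at the package defaults,
    shared across tests that only read it."""
    from advicerl import GroupConfig, generate_cohort

    config = GroupConfig(model_id="M7", study_id="S3", n_participants=6)
    return generate_cohort(config, rng_seed=123)


@pytest.fixture(scope="session")
def small_m2_fit(small_m2_cohort):
    from advicerl import FitConfig, fit_model

    return fit_model("M2", small_m2_cohort, FitConfig(seed=0, n_laplace_draws=100))


@pytest.fixture(scope="session")
def small_m2_cohort():
    from advicerl import GroupConfig, generate_cohort

    config = GroupConfig(model_id="M2", study_id="S3", n_participants=4)
    return generate_cohort(config, rng_seed=321)
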