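import pytest
from hypothesis import HealthCheck, settings

import emdassist as ea

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_params() -> ea.GeneratorParams:
    return ea.GeneratorParams()


@pytest.fixture(scope="session")
def tiny_cohort() -> ea.synthetic.Cohort:
    """One participant including the passive block (300 trials)."""
    params = ea.GeneratorParams(n_participants=1, include_passive=True, seed=11)
    return ea.generate_cohort(params)


@pytest.fixture(scope="session")
def small_metrics():
    """Tidy metrics for a 4-participant cohort at default conditions."""
    params = ea.GeneratorParams(n_participants=4, seed=42)
    return ea.cohort_metrics(params)


@pytest.fixture(scope="session")
def small_models(small_metrics):
    return ea.analyze_outcomes(small_metrics)
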