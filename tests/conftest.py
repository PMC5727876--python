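import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded default-spec cohort at the study's size."""
    from ugib_triage import default_spec, generate_cohort

    return generate_cohort(default_spec(n=590), seed=7)


@pytest.fixture(scope="session")
def large_cohort():
    """A large seeded cohort for properties that need tight sampling error."""
    from ugib_triage import default_spec, generate_cohort

    return generate_cohort(default_spec(n=20000), seed=11, keep_latent=True)
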