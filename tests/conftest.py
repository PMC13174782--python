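import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "latvar",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("latvar")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def scenario_cohort():
    """A small scenario cohort shared across tests (no failures, n=60)."""
    import dataclasses

    from latvar import generate_cohort, reference_scenario

    cfg = dataclasses.replace(reference_scenario(n_participants=60),
                              failure_rates={}, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def scenario_li(scenario_cohort):
    from latvar import assemble_li_matrix

    return assemble_li_matrix(scenario_cohort, exclusion_policy="listwise")
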