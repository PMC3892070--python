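from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def small_cohort():
    """A deterministic small synthetic cohort for cross-module tests."""
    from lbpanel.simulate import CohortConfig, generate_cohort

    config = CohortConfig(
        n_invited=60,
        n_declined=4,
        n_low_response=4,
        cell_missing_prob=0.02,
        seed=7,
    )
    return config, generate_cohort(config)


@pytest.fixture()
def default_cohort():
    """The full-size default cohort (293 invited), generated once per test."""
    from lbpanel.simulate import CohortConfig, generate_cohort

    config = CohortConfig(seed=11)
    return config, generate_cohort(config)
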