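"""Shared fixtures: one small synthetic cohort reused across the suite."""

import pytest

from phenosense.pipeline import extract_all_blocks
from phenosense.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(
        n_participants=12,
        n_cohorts=3,
        days_per_participant=3,
        sc_sample_rate=1.0,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_blocks(small_bundle):
    return extract_all_blocks(small_bundle, seed=3)
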