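import numpy as np
import pytest

from anestherm.synthetic import CohortConfig, Condition, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """Two-group cohort kept small enough for fast end-to-end tests."""
    return CohortConfig(
        conditions=[
            Condition(25.0, 0.8, group_label="mild"),
            Condition(25.0, 1.4, group_label="deep"),
        ],
        n_per_group=2,
        eeg_rate=250.0,
        pre_min=4.0,
        post_margin_min=1.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
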