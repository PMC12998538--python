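import numpy as np
import pytest

from noctvar import CohortConfig


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig()


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort for fast end-to-end runs (same anchors, fewer subjects)."""
    return CohortConfig(
        n_insomnia=12,
        n_control=8,
        n_nights=14,
        weekly_adherence_insomnia=(0.9, 0.8),
        weekly_adherence_control=(0.85, 0.8),
    )
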