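import numpy as np
import pytest

from milsurv.synth import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny cohort shared by read-only tests."""
    cfg = CohortConfig(
        n_patients=60,
        feature_dim=8,
        tiles_per_patient=(5, 12),
        informative_fraction=0.3,
        signal_strength=1.5,
        beta_true=1.0,
        censor_rate=0.15,
        seed=7,
    )
    return generate_cohort(cfg, name="tiny")
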