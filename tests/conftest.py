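"""Shared fixtures: small cohorts, a trained classifier, raw-mode streams."""

import numpy as np
import pytest

from wardsense import (
    SimulationConfig,
    generate_cohort,
    sample_regime_windows,
    train_reference_classifier,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """12 patients over 10 days, window mode."""
    return SimulationConfig(n_patients=12, n_days=10, p_missing_day=0.1, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def full_cohort():
    """Protocol-scale cohort: 110 patients over 21 days, window mode."""
    return generate_cohort(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def raw_config() -> SimulationConfig:
    """Raw-signal mode with a short wear window to keep streams small."""
    return SimulationConfig(
        n_patients=2,
        n_days=2,
        mode="raw",
        wear_start="09:00",
        wear_end="10:00",
        p_missing_day=0.0,
        seed=13,
    )


@pytest.fixture(scope="session")
def raw_cohort(raw_config):
    return generate_cohort(raw_config)


@pytest.fixture(scope="session")
def trained_classifier():
    """Reference classifier trained on 500 windows per activity class."""
    cfg = SimulationConfig()
    train = sample_regime_windows(cfg, n_per_class=500, seed=101)
    return train_reference_classifier(train, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
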