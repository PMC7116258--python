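import numpy as np
import pytest

from pdbiotype.synthetic import OUTCOMES, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest planted-biotype cohort shared across read-only tests."""
    cfg = SimulationConfig(n_pd=80, n_hc=40, grid_shape=(12, 12, 12), seed=42)
    maps, cohort, truth = simulate_cohort(cfg)
    return cfg, maps, cohort, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def null_config():
    """Cohort configuration with no planted signal and no score links."""
    return SimulationConfig(
        n_pd=300,
        n_hc=2,
        grid_shape=(10, 10, 20),
        effect_size=0.0,
        severity_sd=0.0,
        score_link={k: 0.0 for k in OUTCOMES},
        seed=0,
    )
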