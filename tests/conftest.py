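import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def drift_experiment():
    """A drift-only (s = 0) simulated experiment shared across tests."""
    from poolscan.simulate import SimConfig, simulate_experiment

    config = SimConfig(
        n_sites=4000, selected_fraction=0.0, selection_coefficient=0.0, seed=7
    )
    experiment = simulate_experiment(config)
    return experiment.subset(experiment.polymorphic_mask())


@pytest.fixture(scope="session")
def selection_experiment():
    """5% of sites under selection (s = 0.1) in the UF regime only."""
    from poolscan.simulate import SimConfig, simulate_experiment

    config = SimConfig(n_sites=4000, seed=11)
    experiment = simulate_experiment(config)
    return experiment.subset(experiment.polymorphic_mask())
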