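import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20120520)


@pytest.fixture(scope="session")
def small_batch():
    """A 30-locus clean batch exercising every scenario, shared across tests."""
    from svadel.simulate import SimulationConfig, simulate_batch

    cfg = SimulationConfig(seed=7, n_loci=30, substitution_rate=0.0)
    return simulate_batch(cfg)


@pytest.fixture(scope="session")
def small_batch_calls(small_batch):
    from svadel.pipeline import run_stages

    return run_stages(
        small_batch.derived_genome,
        small_batch.ancestral_genome,
        small_batch.repeat_features("derived"),
        small_batch.repeat_features("ancestral"),
        small_batch.elements("ancestral"),
    )
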