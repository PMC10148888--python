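import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def tiny_dataset():
    from helpers import tiny_trial

    return tiny_trial()


@pytest.fixture(scope="session")
def small_trial():
    """A scaled-down default-parameter trial shared across tests."""
    from pwmmrm.simulate import SimConfig, generate_trial

    cfg = SimConfig(arm_sizes=(40, 40, 40), visit_weeks=(2, 4, 8))
    return generate_trial(cfg, seed=11)
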