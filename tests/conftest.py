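import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bundle():
    """One default-condition simulated dataset shared by the heavier tests."""
    from supergene_scan.simdata import SimConfig, simulate_dataset

    return simulate_dataset(SimConfig(seed=11))
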