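import pytest

from ampliclean import default_demo_config, simulate_sample_set


@pytest.fixture()
def demo_config():
    return default_demo_config()


@pytest.fixture(scope="session")
def simulated_dataset():
    """One shared medium-size simulated run (3 samples x 200 reads)."""
    config = default_demo_config()
    records, truths = simulate_sample_set(config, 200, seed=11)
    return config, records, truths
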