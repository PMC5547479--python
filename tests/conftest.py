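import pytest

from poolai import simgen


@pytest.fixture(scope="session")
def small_config():
    return simgen.SimConfig(seed=11, n_sites=600, n_genes=18, n_lncrnas=4)


@pytest.fixture(scope="session")
def small_study(small_config):
    """One modest synthetic study shared across read-only tests."""
    return simgen.simulate_study(small_config)
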