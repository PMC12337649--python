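import numpy as np
import pytest

from icepools import CampaignAnalysis, SimConfig, simulate_campaign


@pytest.fixture(scope="session")
def noise_free_config():
    """Generator with every stochastic perturbation switched off."""
    return SimConfig(
        seed=7,
        noise_cv=0.0,
        process_sd_N=0.0,
        process_sd_Si=0.0,
        coupling_r=0.0,
        current_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def noise_free_tables(noise_free_config):
    return simulate_campaign(noise_free_config)


@pytest.fixture(scope="session")
def default_tables():
    return simulate_campaign(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_results(default_tables):
    return CampaignAnalysis(default_tables).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
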