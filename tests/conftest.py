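import numpy as np
import pytest
from hypothesis import settings

from invscan import PipelineConfig, SimConfig, run_all, simulate

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

SIM_SEED = 1  # fixed study-conditions seed for the shared fixtures


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic study design (shared across tests)."""
    return simulate(SimConfig(seed=SIM_SEED))


@pytest.fixture(scope="session")
def pipeline_result():
    """Full pipeline run on the default simulation (shared across tests)."""
    return run_all(PipelineConfig(sim=SimConfig(), seed=SIM_SEED))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
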