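import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rvdys.simulate import SimulationConfig, generate_cohort

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_small():
    """A small default-configuration synthetic cohort."""
    return generate_cohort(SimulationConfig(n=60, seed=42))


@pytest.fixture(scope="session")
def sim_clean():
    """Noise-free cohort with all three views present for every patient."""
    return generate_cohort(SimulationConfig(
        n=40, seed=7, noise_sd=0.0, rv3ch_missing_frac=0.0))
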