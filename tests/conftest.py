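import numpy as np
import pytest

from anttraffic import GeneratorConfig, MicroParams
from anttraffic.synthetic_data import generate_macroscopic, generate_tracked


@pytest.fixture(scope="session")
def params():
    return MicroParams()


@pytest.fixture(scope="session")
def tracked_noisy(params):
    """8,000 tracked records at the default calibration, fixed seed."""
    return generate_tracked(8000, params=params, config=GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def tracked_noiseless(params):
    """Deterministic tracked records: mean contacts, no timing noise."""
    cfg = GeneratorConfig(
        seed=1, contact_noise=False, travel_noise_sd=0.0, uturn_prob=0.0
    )
    return generate_tracked(4000, params=params, config=cfg)


@pytest.fixture(scope="session")
def macro_uniform(params):
    """Per-second observations with iid uniform densities, Poisson counts."""
    cfg = GeneratorConfig(
        seed=5, density_profile="uniform", density_max=16.0, duration=5000
    )
    return generate_macroscopic(cfg, params)
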