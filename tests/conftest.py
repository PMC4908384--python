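import numpy as np
import pytest

from optocochlea import ExperimentConfig, build_heating_source
from optocochlea.confinement import WATER

FIBER_RADIUS = 52.5e-6  # 105 um core


@pytest.fixture(scope="session")
def water():
    return WATER


@pytest.fixture(scope="session")
def source_mu10():
    """Beer-Lambert source for mu_a = 10 cm^-1 from the 105 um fiber."""
    return build_heating_source(FIBER_RADIUS, 10.0)


@pytest.fixture(scope="session")
def fast_config():
    """Default study config with reduced sweep grids for test runtime."""
    return ExperimentConfig(
        energy_sweep_durations_s=(5e-9, 5e-6, 2e-5, 5e-5, 1e-4, 2e-4),
        power_sweep_durations_s=(1e-5, 4e-5, 1e-4, 2e-3),
        absorption_sweep_mu_a_cm1=(1.34, 8.89, 57.5),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
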