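import warnings

import numpy as np
import pytest

from spraytrack.synthetic_data import (
    CageModel,
    SyntheticConfig,
    WaterModel,
    default_schedule,
    simulate_cage_experiment,
    simulate_monitoring,
)

# statsmodels ARIMA emits copious convergence chatter on tiny series;
# tests assert on results, not warnings, unless they say otherwise.
warnings.filterwarnings("ignore", category=UserWarning, module="statsmodels")
warnings.filterwarnings("ignore", category=RuntimeWarning, module="statsmodels")


# small ARIMA order grid used wherever runtime matters more than order choice
SMALL_GRID = tuple((p, d, q) for p in range(2) for d in range(2) for q in range(2))


@pytest.fixture(scope="session")
def base_config():
    return SyntheticConfig(seed=20130617)


@pytest.fixture(scope="session")
def monitoring_data(base_config):
    return simulate_monitoring(base_config)


@pytest.fixture(scope="session")
def trap_records(monitoring_data):
    return monitoring_data[0]


@pytest.fixture(scope="session")
def weather_records(monitoring_data):
    return monitoring_data[1]


@pytest.fixture(scope="session")
def schedule(base_config):
    return default_schedule(base_config)


@pytest.fixture(scope="session")
def cage_records(base_config):
    return simulate_cage_experiment(base_config, validation_distances=(13.0, 41.0))


@pytest.fixture(scope="session")
def diverged_traps():
    """Monitoring data with a real mid-season suppression of the treated site."""
    config = SyntheticConfig(seed=11, treatment_effect=0.3, divergence_index=15)
    traps, _ = simulate_monitoring(config)
    return traps
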