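import numpy as np
import pytest

from fastnose import (HeaterCache, OdorantPanel, SimulationConfig,
                      default_sensor_array, experiment_modes,
                      simulate_recording)
from fastnose.protocol import Trial


@pytest.fixture(scope="session")
def panel():
    return OdorantPanel.default()


@pytest.fixture(scope="session")
def sensors():
    return default_sensor_array()


@pytest.fixture(scope="session")
def sim_config_b():
    """Experiment-B simulation config (sensors 1-4 constant, 5-8 cycled)."""
    return SimulationConfig(modes=experiment_modes("B"))


@pytest.fixture(scope="session")
def heater_cache_b(sim_config_b):
    return HeaterCache(sim_config_b, seed=0)


@pytest.fixture(scope="session")
def pulse_recording(sim_config_b, heater_cache_b):
    """One digitized 1 s full-concentration IA pulse (experiment B)."""
    trial = Trial("pulse", ("IA",), 1000, 100.0)
    return simulate_recording(trial, sim_config_b, seed=11,
                              heater_cache=heater_cache_b)


@pytest.fixture(scope="session")
def blank_recording(sim_config_b, heater_cache_b):
    trial = Trial("pulse", ("blank",), 1000, 100.0)
    return simulate_recording(trial, sim_config_b, seed=12,
                              heater_cache=heater_cache_b)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
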