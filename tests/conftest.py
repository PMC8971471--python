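import numpy as np
import pytest

from safyassim.safy_core import SafyParams, WeatherSeries
from safyassim.synthetic_data import TrialDesign, generate_trial, generate_weather


@pytest.fixture
def default_params() -> SafyParams:
    return SafyParams(d0=10, elue=2.0, senescence_threshold=1000.0)


@pytest.fixture
def constant_weather() -> WeatherSeries:
    """300 days of constant optimum temperature and steady radiation."""
    n = 300
    return WeatherSeries(day=np.arange(n), ta=np.full(n, 18.0), rg=np.full(n, 20.0))


@pytest.fixture(scope="session")
def season_weather() -> WeatherSeries:
    return generate_weather(season_length=280, seed=3)


@pytest.fixture(scope="session")
def noise_free_trial(season_weather):
    design = TrialDesign(
        seed=5, sigma_lai=0.0, dam_cv=0.0, sigma_yield=0.0, sigma_reflectance=0.0
    )
    return generate_trial(design, season_weather)


@pytest.fixture(scope="session")
def noisy_trial(season_weather):
    return generate_trial(TrialDesign(seed=11), season_weather)
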