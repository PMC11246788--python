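"""Shared fixtures: small constructed series and scenario shortcuts."""

import numpy as np
import pandas as pd
import pytest

from nivophen.microclimate import TemperatureSeries
from nivophen.synthetic_data import (CameraSpec, ScenarioConfig, SiteSpec,
                                     default_species_programs)


def hourly_series(daily_means, year=2020, start_doy=150, plot_id="p1"):
    """Constant-within-day hourly series with the given daily means."""
    start = pd.Timestamp(year=year, month=1, day=1) + pd.Timedelta(days=start_doy - 1)
    idx = pd.date_range(start, periods=len(daily_means) * 24, freq="h")
    temps = np.repeat(np.asarray(daily_means, dtype=float), 24)
    return TemperatureSeries(plot_id=plot_id, timestamps=idx, temp_c=temps)


@pytest.fixture
def melt_at_175():
    """Series below 2 °C until DOY 175, sustained 8 °C after."""
    means = [1.0] * 25 + [8.0] * 40      # DOYs 150..174 cold, 175.. warm
    return hourly_series(means, start_doy=150)


@pytest.fixture
def small_scenario():
    """One small site, one year — fast enough for per-test simulation."""
    site = SiteSpec(name="late", n_plots=2,
                    melt_doy_by_year={2020: 180},
                    summer_mean_temp=10.0, plot_melt_jitter_days=0)
    return ScenarioConfig(sites=[site], years=[2020],
                          species=default_species_programs()[:2],
                          seed=7, noise_sd_phase=0.0, camera=CameraSpec())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
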