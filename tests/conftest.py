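import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from circstrain.series import EpochSeries

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def make_series(activity, light=None, epoch_min=10, start="2019-04-01 00:00:00",
                wear=None, device="Actiwatch2", subject_id="T001"):
    activity = np.asarray(activity, dtype=float)
    if light is None:
        light = np.full_like(activity, 100.0)
        light[np.isnan(activity)] = np.nan
    if wear is None:
        wear = ~np.isnan(activity)
    return EpochSeries(subject_id=subject_id, start_time=pd.Timestamp(start),
                       epoch_min=epoch_min, activity=activity,
                       light=np.asarray(light, dtype=float),
                       wear=np.asarray(wear, dtype=bool), device=device)


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def seven_day_sinusoid():
    """Noise-free 24-h sinusoid sampled at 10-min epochs over 7 days."""
    t = np.arange(7 * 144) * (10 / 60.0)
    x = 10.0 + 5.0 * np.cos(2 * np.pi * t / 24.0)
    return make_series(x)


@pytest.fixture
def tiled_week():
    """An arbitrary non-constant daily pattern repeated identically 7 times."""
    rng = np.random.default_rng(11)
    day = rng.gamma(2.0, 50.0, 144)
    return make_series(np.tile(day, 7))
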