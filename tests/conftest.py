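import datetime as dt

import numpy as np
import pytest

from doublecrop.preprocess import preprocess
from doublecrop.synthetic_phenology import default_battery
from doublecrop.timeseries_io import FieldMeta, FieldSeries, Observation

BATTERY_SEED = 20250901


def make_series(doys, values, year=2017, field_id="F0", **meta_kw):
    """Build a FieldSeries from day-of-year / value pairs."""
    jan1 = dt.date(year, 1, 1)
    obs = tuple(
        Observation(jan1 + dt.timedelta(days=int(d) - 1), float(v))
        for d, v in zip(doys, values)
    )
    return FieldSeries(
        meta=FieldMeta(field_id=field_id, **meta_kw), year=year, observations=obs
    )


@pytest.fixture(scope="session")
def battery():
    """The standard named datasets, generated once per test session."""
    return default_battery(BATTERY_SEED)


@pytest.fixture(scope="session")
def clean_battery(battery):
    return battery["CLEAN"]


@pytest.fixture(scope="session")
def noisy_battery(battery):
    return battery["NOISY"]


@pytest.fixture(scope="session")
def confuser_battery(battery):
    return battery["CONFUSER"]


@pytest.fixture(scope="session")
def noisy_smoothed(noisy_battery):
    series, truths = noisy_battery
    return [preprocess(s) for s in series], truths


@pytest.fixture(scope="session")
def confuser_smoothed(confuser_battery):
    series, truths = confuser_battery
    return [preprocess(s) for s in series], truths


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
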