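import numpy as np
import pandas as pd
import pytest

from tidalflux.timeseries_io import HourlyCountSeries

START = pd.Timestamp("2014-01-01 00:00", tz="UTC")


@pytest.fixture
def start():
    return START


def make_series(values, start=START) -> HourlyCountSeries:
    """Hourly series from a list of values; NaN marks a missing hour."""
    return HourlyCountSeries.from_observations(start, np.asarray(values, dtype=float))


@pytest.fixture
def sinusoid_series():
    """20 days of a noiseless 24-h sinusoid (3*sin + 5) with a 6-h gap."""
    t = np.arange(24 * 20, dtype=float)
    y = 3.0 * np.sin(2.0 * np.pi * t / 24.0) + 5.0
    v = y.copy()
    v[100:106] = np.nan
    return make_series(v), y
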