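import numpy as np
import pandas as pd
import pytest

from thermoload import (
    MicroclimateSeries,
    TDTParams,
    calibrate_repair,
)


@pytest.fixture
def pollen():
    return TDTParams(ctmax=46.0, z=3.0)


@pytest.fixture
def pollen_repair(pollen):
    return calibrate_repair(pollen, t_cross=31.0)


def make_series(temps, step_minutes=1.0, height=50.0, start="2024-01-01", **extras):
    """Single-height series from a temperature array (helper for tests)."""
    temps = np.asarray(temps, dtype=float)
    times = pd.date_range(start, periods=temps.size, freq=pd.Timedelta(minutes=step_minutes))
    return MicroclimateSeries(times=times, temps={height: temps}, **extras)


def constant_series(temperature, n_steps, step_minutes=1.0, height=50.0):
    return make_series(np.full(n_steps, float(temperature)), step_minutes, height)
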