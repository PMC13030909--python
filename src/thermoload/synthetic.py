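"""Synthetic weather, microclimate and assay generators.

Everything the pipeline consumes can be generated here with known ground
truth: multi-day diurnal air-temperature series (with heatwave pulses and
rain days), derived height-stratified microclimates, and TDT assay datasets
for parameter-recovery tests.

The diurnal shape is a half-sine rise from the day's tmin at sunrise to its
tmax at the solar peak, followed by linear night cooling to the next
sunrise. The solar proxy is a half-sine over daylight that peaks at the same
instant as the temperature, so on a clear dry day the derived surface trace
peaks exactly ``a0 * (1 - shade)`` above the air peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, InvalidInputError
from .microclimate import (
    AIR_REFERENCE_HEIGHT_CM,
    MicroclimateSeries,
    ProfileParams,
    apply_profile,
)
from .tdt import TDTAssay, TDTParams, failure_time

__all__ = [
    "WeatherScenario",
    "generate_weather",
    "generate_microclimate",
    "generate_tdt_assay",
    "scenario_from_dict",
    "scenario_to_dict",
    "load_scenario",
    "list_fixture_scenarios",
]

_MINUTES_PER_DAY = 1440.0


@dataclass(frozen=True)
class WeatherScenario:
    """Generative description of a synthetic weather experiment.

    ``tmin`` / ``tmax`` may be scalars (every day alike) or per-day
    sequences of length ``n_days``. Heatwave days get ``tmax_boost`` added
    to their maximum; rain days have zero solar input and reset soil
    dryness to 0, after which it relaxes linearly back to 1 over
    ``dryness_recovery_days``.
    """

    n_days: int
    tmin: float | Sequence[float] = 18.0
    tmax: float | Sequence[float] = 30.0
    heatwave_days: frozenset = frozenset()
    tmax_boost: float = 12.0
    rain_days: frozenset = frozenset()
    daylength_hours: float = 14.0
    peak_hour: float = 14.0
    dryness_recovery_days: float = 2.0
    step_minutes: float = 10.0
    start: str = "2024-01-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ConfigurationError("n_days must be >= 1")
        if not (0.0 < self.daylength_hours < 24.0):
            raise ConfigurationError(
                f"daylength_hours must lie in (0, 24), got {self.daylength_hours!r}"
            )
        half = self.daylength_hours / 2.0
        if self.peak_hour - half < 0.0 or self.peak_hour + half > 24.0:
            raise ConfigurationError(
                "daylight window (peak_hour +/- daylength/2) must fit within the day"
            )
        if self.step_minutes <= 0:
            raise ConfigurationError("step_minutes must be > 0")
        if self.dryness_recovery_days < 0:
            raise ConfigurationError("dryness_recovery_days must be >= 0")
        object.__setattr__(self, "heatwave_days", frozenset(int(d) for d in self.heatwave_days))
        object.__setattr__(self, "rain_days", frozenset(int(d) for d in self.rain_days))
        for name in ("heatwave_days", "rain_days"):
            days = getattr(self, name)
            if any(d < 0 or d >= self.n_days for d in days):
                raise ConfigurationError(f"{name} indices must lie in [0, {self.n_days})")
        tmin = self._per_day("tmin", self.tmin)
        tmax = self._per_day("tmax", self.tmax)
        if np.any(tmax < tmin):
            raise ConfigurationError("tmax must be >= tmin on every day")

    def _per_day(self, name: str, value) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(value, dtype=float))
        if arr.size == 1:
            arr = np.full(self.n_days, arr[0])
        if arr.size != self.n_days:
            raise ConfigurationError(
                f"{name} must be a scalar or a length-{self.n_days} sequence"
            )
        if not np.all(np.isfinite(arr)):
            raise ConfigurationError(f"{name} must be finite")
        return arr

    def daily_tmin(self) -> np.ndarray:
        return self._per_day("tmin", self.tmin)

    def daily_tmax(self) -> np.ndarray:
        """Per-day maxima with the heatwave boost applied."""
        tmax = self._per_day("tmax", self.tmax)
        for d in self.heatwave_days:
            tmax[d] += self.tmax_boost
        return tmax


def generate_weather(scenario: WeatherScenario) -> MicroclimateSeries:
    """Generate the 1.2 m air series with solar, dryness and rain traces.

    Deterministic: the same scenario always produces the identical series.
    """
    n_steps = int(round(scenario.n_days * _MINUTES_PER_DAY / scenario.step_minutes))
    t = np.arange(n_steps) * scenario.step_minutes  # minutes since start
    times = pd.date_range(
        scenario.start, periods=n_steps, freq=pd.Timedelta(minutes=scenario.step_minutes)
    )

    tmin = scenario.daily_tmin()
    tmax = scenario.daily_tmax()
    sunrise_min = (scenario.peak_hour - scenario.daylength_hours / 2.0) * 60.0
    peak_min = scenario.peak_hour * 60.0

    def day_value(arr: np.ndarray, d: int) -> float:
        return float(arr[min(max(d, 0), scenario.n_days - 1)])

    temp = np.empty(n_steps)
    # anchors: (sunrise_d, tmin_d) --half-sine--> (peak_d, tmax_d)
    #          --linear--> (sunrise_{d+1}, tmin_{d+1});
    # virtual days -1 and n_days reuse the boundary days' values.
    for d in range(-1, scenario.n_days + 1):
        t_sun = d * _MINUTES_PER_DAY + sunrise_min
        t_peak = d * _MINUTES_PER_DAY + peak_min
        t_next_sun = t_sun + _MINUTES_PER_DAY
        v_min, v_max = day_value(tmin, d), day_value(tmax, d)
        v_next_min = day_value(tmin, d + 1)

        rise = (t >= t_sun) & (t < t_peak)
        frac = (t[rise] - t_sun) / (t_peak - t_sun)
        temp[rise] = v_min + (v_max - v_min) * np.sin(0.5 * np.pi * frac)

        fall = (t >= t_peak) & (t < t_next_sun)
        frac = (t[fall] - t_peak) / (t_next_sun - t_peak)
        temp[fall] = v_max + (v_next_min - v_max) * frac

    day_idx = (t // _MINUTES_PER_DAY).astype(int)
    tod = t % _MINUTES_PER_DAY
    x = (tod - sunrise_min) / (scenario.daylength_hours * 60.0)
    solar = np.where((x >= 0.0) & (x <= 1.0), np.sin(np.pi * np.clip(x, 0.0, 1.0)), 0.0)

    rain = np.isin(day_idx, sorted(scenario.rain_days))
    solar[rain] = 0.0

    dryness = np.ones(n_steps)
    recovery_min = scenario.dryness_recovery_days * _MINUTES_PER_DAY
    last_rain_end: float | None = None
    for d in range(scenario.n_days):
        sel = day_idx == d
        if d in scenario.rain_days:
            dryness[sel] = 0.0
            last_rain_end = (d + 1) * _MINUTES_PER_DAY
        elif last_rain_end is not None:
            if recovery_min > 0:
                dryness[sel] = np.minimum(1.0, (t[sel] - last_rain_end) / recovery_min)
            # recovery_min == 0 -> immediately fully dry again

    return MicroclimateSeries(
        times=times,
        temps={AIR_REFERENCE_HEIGHT_CM: temp},
        solar=solar,
        dryness=dryness,
        rain=rain,
    )


def generate_microclimate(
    scenario: WeatherScenario, profile: ProfileParams, heights
) -> MicroclimateSeries:
    """Generate weather and derive temperature traces at ``heights``."""
    return apply_profile(generate_weather(scenario), profile, heights)


def generate_tdt_assay(
    true_params: TDTParams,
    temperatures,
    reps_per_temp: int,
    noise_sd: float,
    seed: int,
) -> TDTAssay:
    """Synthetic static-assay data on the exact TDT line plus log10 noise.

    failure_time = 10 ** (log10(t_fail(T)) + eps), eps ~ Normal(0, noise_sd),
    so the noise model matches the regression model of ``fit_tdt``.
    """
    temps = np.asarray(temperatures, dtype=float)
    if temps.size == 0:
        raise InvalidInputError("temperature list must be non-empty")
    if reps_per_temp < 1:
        raise InvalidInputError("reps_per_temp must be >= 1")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    all_temps = np.repeat(temps, reps_per_temp)
    log_t = np.log10(failure_time(true_params, all_temps))
    eps = rng.normal(0.0, noise_sd, all_temps.size) if noise_sd > 0 else 0.0
    return TDTAssay(temperature=all_temps, failure_time=10.0 ** (log_t + eps))


_SCENARIO_FIELDS = {
    "n_days", "tmin", "tmax", "heatwave_days", "tmax_boost", "rain_days",
    "daylength_hours", "peak_hour", "dryness_recovery_days", "step_minutes",
    "start", "seed",
}


def scenario_from_dict(data: dict) -> WeatherScenario:
    """Build a scenario from a YAML-style mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigurationError(f"scenario must be a mapping, got {type(data).__name__}")
    unknown = set(data) - _SCENARIO_FIELDS
    if unknown:
        raise ConfigurationError(f"unknown scenario field(s): {sorted(unknown)}")
    if "n_days" not in data:
        raise ConfigurationError("scenario.n_days is required")
    kwargs = dict(data)
    for key in ("heatwave_days", "rain_days"):
        if key in kwargs:
            kwargs[key] = frozenset(kwargs[key])
    return WeatherScenario(**kwargs)


def scenario_to_dict(scenario: WeatherScenario) -> dict:
    tmin, tmax = scenario.tmin, scenario.tmax
    return {
        "n_days": scenario.n_days,
        "tmin": list(tmin) if not np.isscalar(tmin) else float(tmin),
        "tmax": list(tmax) if not np.isscalar(tmax) else float(tmax),
        "heatwave_days": sorted(scenario.heatwave_days),
        "tmax_boost": scenario.tmax_boost,
        "rain_days": sorted(scenario.rain_days),
        "daylength_hours": scenario.daylength_hours,
        "peak_hour": scenario.peak_hour,
        "dryness_recovery_days": scenario.dryness_recovery_days,
        "step_minutes": scenario.step_minutes,
        "start": scenario.start,
        "seed": scenario.seed,
    }


def list_fixture_scenarios() -> list[str]:
    """Names of the scenario fixtures bundled with the package."""
    root = resources.files("thermoload") / "fixtures"
    return sorted(
        p.name[: -len(".yaml")]
        for p in root.iterdir()
        if p.name.endswith(".yaml") and p.name.startswith("scenario_")
    )


def load_scenario(name: str) -> WeatherScenario:
    """Load a bundled fixture scenario by name (see list_fixture_scenarios)."""
    path = resources.files("thermoload") / "fixtures" / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise ConfigurationError(
            f"unknown fixture scenario {name!r}; "
            f"available: {list_fixture_scenarios()}"
        ) from None
    return scenario_from_dict(yaml.safe_load(text))
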