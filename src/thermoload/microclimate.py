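"""Height-stratified microclimate temperature series.

Standard weather observations are made at 1.2 m; tissue close to the soil
surface experiences far higher temperatures under solar load. This module
represents uniformly-sampled temperature traces keyed by height above soil,
derives near-surface traces from a 1.2 m air trace via a simple
exponential-decay excess profile, and reads/writes the series as long-format
CSV.

The profile is deliberately simple and calibrated to two exemplar offsets:
on a clear dry unshaded day the soil surface (0 cm) peaks 20 degrees C above
the 1.2 m air temperature and 1 cm above ground peaks 8 degrees C above it.
Full biophysical microclimate models are not re-implemented; their exported
tables are accepted through the CSV reader instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, InvalidInputError

__all__ = [
    "AIR_REFERENCE_HEIGHT_CM",
    "SHADE_MAX",
    "MicroclimateSeries",
    "ProfileParams",
    "vertical_offset",
    "apply_profile",
    "read_microclimate_csv",
    "write_microclimate_csv",
]

#: Height of the standard air-temperature reference trace (cm).
AIR_REFERENCE_HEIGHT_CM = 120.0

#: Upper bound of the configurable canopy shade fraction.
SHADE_MAX = 0.6


@dataclass
class MicroclimateSeries:
    """Uniform-step temperature traces at one or more heights above soil.

    Attributes
    ----------
    times : pandas.DatetimeIndex
        Strictly increasing, uniform-step timestamps.
    temps : dict mapping height (cm) to temperature trace (degrees C)
        Every trace has the same length as ``times``.
    solar : array or None
        Dimensionless solar proxy in [0, 1], one value per timestamp.
    dryness : array or None
        Soil-surface dryness in [0, 1]; 1 = fully dry, 0 = just rained.
    rain : boolean array or None
        Rainfall flag per timestamp.
    """

    times: pd.DatetimeIndex
    temps: dict[float, np.ndarray]
    solar: np.ndarray | None = None
    dryness: np.ndarray | None = None
    rain: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        n = len(self.times)
        if n < 2:
            raise InvalidInputError("series needs at least 2 timestamps")
        steps = np.diff(self.times.asi8)
        if not np.all(steps > 0):
            raise InvalidInputError("timestamps must be strictly increasing")
        if np.unique(steps).size != 1:
            raise InvalidInputError("timestamps must be uniform-step")
        if not self.temps:
            raise InvalidInputError("series must carry at least one height trace")
        temps: dict[float, np.ndarray] = {}
        for height, trace in self.temps.items():
            h = float(height)
            if h < 0:
                raise InvalidInputError(f"height must be >= 0 cm, got {h}")
            arr = np.asarray(trace, dtype=float)
            if arr.shape != (n,):
                raise InvalidInputError(
                    f"trace at {h} cm has length {arr.size}, expected {n}"
                )
            temps[h] = arr
        self.temps = temps
        for name in ("solar", "dryness"):
            trace = getattr(self, name)
            if trace is None:
                continue
            arr = np.asarray(trace, dtype=float)
            if arr.shape != (n,):
                raise InvalidInputError(f"{name} trace length mismatch")
            if np.any((arr < 0) | (arr > 1)):
                raise InvalidInputError(f"{name} values must lie in [0, 1]")
            setattr(self, name, arr)
        if self.rain is not None:
            arr = np.asarray(self.rain, dtype=bool)
            if arr.shape != (n,):
                raise InvalidInputError("rain trace length mismatch")
            self.rain = arr

    def __len__(self) -> int:
        return len(self.times)

    @property
    def step_minutes(self) -> float:
        return float((self.times[1] - self.times[0]) / pd.Timedelta(minutes=1))

    @property
    def heights(self) -> list[float]:
        return sorted(self.temps)

    def trace_at(self, height_cm: float) -> np.ndarray:
        """Temperature trace at ``height_cm``, matched to 1e-6 cm."""
        for h, trace in self.temps.items():
            if abs(h - float(height_cm)) < 1e-6:
                return trace
        raise ConfigurationError(
            f"no trace at height {height_cm} cm; available heights: {self.heights}"
        )

    def has_height(self, height_cm: float) -> bool:
        return any(abs(h - float(height_cm)) < 1e-6 for h in self.temps)

    def shifted(self, delta_c: float) -> "MicroclimateSeries":
        """Copy with every temperature trace shifted by ``delta_c``."""
        return replace(
            self, temps={h: t + delta_c for h, t in self.temps.items()}
        )


@dataclass(frozen=True)
class ProfileParams:
    """Vertical temperature-excess profile above the soil surface.

    Daytime excess over the 1.2 m air temperature decays exponentially with
    height:  a0 * solar * dryness * (1 - shade) * exp(-h / h_scale).
    The defaults reproduce the +20 degree surface and +8 degree 1 cm peak
    excesses (h_scale = 1/ln(20/8)). At night (zero solar) the surface
    radiatively cools ``night_deficit`` degrees below air, with the same
    height decay.
    """

    a0: float = 20.0
    h_scale: float = 1.0 / math.log(2.5)
    night_deficit: float = 2.0
    shade_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a0) and self.a0 >= 0):
            raise InvalidInputError(f"a0 must be >= 0, got {self.a0!r}")
        if not (np.isfinite(self.h_scale) and self.h_scale > 0):
            raise InvalidInputError(f"h_scale must be > 0, got {self.h_scale!r}")
        if not (np.isfinite(self.night_deficit) and self.night_deficit >= 0):
            raise InvalidInputError("night_deficit must be >= 0")
        if not (0.0 <= self.shade_fraction <= SHADE_MAX):
            raise InvalidInputError(
                f"shade_fraction must lie in [0, {SHADE_MAX}], got {self.shade_fraction!r}"
            )


def vertical_offset(
    profile: ProfileParams, height_cm: float, solar, dryness
) -> float | np.ndarray:
    """Temperature excess (degrees C) at ``height_cm`` over the air reference.

    ``solar`` and ``dryness`` must lie in [0, 1]; arrays broadcast. Positive
    under solar load, ``-night_deficit * exp(-h/h_scale)`` when solar is 0.
    """
    if not (np.isfinite(height_cm) and height_cm >= 0):
        raise InvalidInputError(f"height must be >= 0 cm, got {height_cm!r}")
    sol = np.asarray(solar, dtype=float)
    dry = np.asarray(dryness, dtype=float)
    for name, arr in (("solar", sol), ("dryness", dry)):
        if not np.all(np.isfinite(arr)) or np.any((arr < 0) | (arr > 1)):
            raise InvalidInputError(f"{name} must lie in [0, 1]")
    decay = math.exp(-float(height_cm) / profile.h_scale)
    day = profile.a0 * sol * dry * (1.0 - profile.shade_fraction) * decay
    out = np.where(sol > 0, day, -profile.night_deficit * decay)
    return float(out) if out.ndim == 0 else out


def apply_profile(
    air: MicroclimateSeries, profile: ProfileParams, heights
) -> MicroclimateSeries:
    """Derive traces at ``heights`` from the 1.2 m air trace.

    T(h, t) = T_air(t) + vertical_offset(h, solar(t), dryness(t)).
    The air reference trace is carried through unchanged.
    """
    if not air.has_height(AIR_REFERENCE_HEIGHT_CM):
        raise ConfigurationError(
            f"air series must contain the {AIR_REFERENCE_HEIGHT_CM:g} cm "
            f"reference trace; available heights: {air.heights}"
        )
    if air.solar is None or air.dryness is None:
        raise ConfigurationError(
            "deriving height traces requires solar and dryness traces on the air series"
        )
    t_air = air.trace_at(AIR_REFERENCE_HEIGHT_CM)
    temps = {AIR_REFERENCE_HEIGHT_CM: t_air.copy()}
    for h in heights:
        h = float(h)
        if abs(h - AIR_REFERENCE_HEIGHT_CM) < 1e-6:
            continue
        temps[h] = t_air + vertical_offset(profile, h, air.solar, air.dryness)
    return MicroclimateSeries(
        times=air.times,
        temps=temps,
        solar=None if air.solar is None else air.solar.copy(),
        dryness=None if air.dryness is None else air.dryness.copy(),
        rain=None if air.rain is None else air.rain.copy(),
    )


_REQUIRED_COLUMNS = ("datetime", "height_cm", "temp_C")
_OPTIONAL_COLUMNS = ("solar", "dryness", "rain")


def write_microclimate_csv(series: MicroclimateSeries, path) -> None:
    """Serialize a series as long-format CSV sorted by (height, time).

    Columns: datetime, height_cm, temp_C and, when present on the series,
    solar, dryness, rain. Floats use shortest-round-trip formatting so the
    read/write cycle is lossless.
    """
    frames = []
    for h in series.heights:
        data = {
            "datetime": series.times.strftime("%Y-%m-%dT%H:%M:%S"),
            "height_cm": h,
            "temp_C": series.temps[h],
        }
        if series.solar is not None:
            data["solar"] = series.solar
        if series.dryness is not None:
            data["dryness"] = series.dryness
        if series.rain is not None:
            data["rain"] = series.rain.astype(int)
        frames.append(pd.DataFrame(data))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_microclimate_csv(path, strict: bool = False) -> MicroclimateSeries:
    """Parse a long-format microclimate CSV.

    With ``strict=True`` rows must already be sorted by (height_cm,
    datetime); otherwise they are deterministically re-sorted. Validation
    failures report the offending CSV row numbers (1-based, header = row 1).
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; "
            f"found columns {list(frame.columns)}"
        )
    if frame.empty:
        raise FormatError(f"{path}: no data rows")
    parsed = pd.to_datetime(frame["datetime"], errors="coerce", format="ISO8601")
    bad = np.flatnonzero(parsed.isna().to_numpy())
    if bad.size:
        rows = ", ".join(str(i + 2) for i in bad[:5])
        raise FormatError(f"{path}: unparseable datetime at row(s) {rows}")
    frame = frame.assign(datetime=parsed)

    order = np.lexsort((frame["datetime"].to_numpy(), frame["height_cm"].to_numpy()))
    if not np.array_equal(order, np.arange(len(frame))):
        if strict:
            first = int(np.flatnonzero(order != np.arange(len(frame)))[0])
            raise FormatError(
                f"{path}: rows not sorted by (height_cm, datetime); "
                f"first out-of-order row {first + 2} (strict mode)"
            )
        frame = frame.iloc[order].reset_index(drop=True)

    heights = frame["height_cm"].unique()
    times = None
    temps: dict[float, np.ndarray] = {}
    extras: dict[str, np.ndarray] = {}
    for h in heights:
        block = frame[frame["height_cm"] == h]
        t = pd.DatetimeIndex(block["datetime"])
        if t.has_duplicates:
            dup = t[t.duplicated()][0]
            raise FormatError(f"{path}: duplicate timestamp {dup} at height {h} cm")
        if times is None:
            times = t
            steps = np.unique(np.diff(t.asi8))
            if len(t) < 2 or steps.size != 1:
                raise FormatError(
                    f"{path}: timestamps at height {h} cm are not uniform-step"
                )
            for col in _OPTIONAL_COLUMNS:
                if col in block.columns:
                    extras[col] = block[col].to_numpy()
        elif not t.equals(times):
            raise FormatError(
                f"{path}: height {h} cm covers different timestamps than "
                f"height {heights[0]} cm"
            )
        temps[float(h)] = block["temp_C"].to_numpy(dtype=float)
    return MicroclimateSeries(
        times=times,
        temps=temps,
        solar=extras.get("solar"),
        dryness=extras.get("dryness"),
        rain=None if "rain" not in extras else extras["rain"].astype(bool),
    )
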