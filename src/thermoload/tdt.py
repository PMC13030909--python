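"""Thermal death time (TDT) curves.

A TDT curve is the log-linear relationship between exposure temperature and
the time until physiological failure under constant exposure:

    t_fail(T) = t_ref * 10 ** ((ctmax - T) / z)

where ``ctmax`` is the temperature tolerated for exactly the reference
duration ``t_ref`` (1 minute by default) and ``z`` is the thermal
sensitivity: the drop in tolerated temperature per tenfold increase in
exposure duration. Equivalently, tolerated temperature declines linearly
with log10 duration.

The module evaluates the curve in both directions, derives the instantaneous
damage rate (the reciprocal of failure time, so a constant exposure of
length ``t_fail(T)`` accumulates exactly one unit of damage), and fits the
curve to static-assay data by ordinary least squares of log10 failure time
on temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateDesignError, InvalidInputError, NonTDTBehaviourError

__all__ = [
    "TDTParams",
    "TDTAssay",
    "TDTFit",
    "DEFAULT_STAGE_TDT",
    "failure_time",
    "tolerated_temperature",
    "damage_rate",
    "fit_tdt",
]


@dataclass(frozen=True)
class TDTParams:
    """Parameters of one TDT curve.

    Attributes
    ----------
    ctmax : float
        Temperature (degrees C) tolerated for exactly ``t_ref`` minutes.
    z : float
        Sensitivity (degrees C per decade of log10 exposure duration); > 0.
    t_ref : float
        Reference duration in minutes (default 1); > 0.
    """

    ctmax: float
    z: float
    t_ref: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.ctmax):
            raise InvalidInputError(f"ctmax must be finite, got {self.ctmax!r}")
        if not (np.isfinite(self.z) and self.z > 0):
            raise InvalidInputError(f"z must be finite and > 0, got {self.z!r}")
        if not (np.isfinite(self.t_ref) and self.t_ref > 0):
            raise InvalidInputError(f"t_ref must be finite and > 0, got {self.t_ref!r}")


#: Default stage-mean curves, ordered by increasing heat tolerance:
#: pollen is the most sensitive, imbibed seed the most tolerant.
DEFAULT_STAGE_TDT: dict[str, TDTParams] = {
    "pollen": TDTParams(ctmax=46.0, z=3.0),
    "seedling": TDTParams(ctmax=52.0, z=3.5),
    "seed": TDTParams(ctmax=58.0, z=4.5),
}


def _check_temperature(temperature) -> np.ndarray:
    temp = np.asarray(temperature, dtype=float)
    if not np.all(np.isfinite(temp)):
        raise InvalidInputError("temperature must be finite")
    return temp


def failure_time(params: TDTParams, temperature) -> float | np.ndarray:
    """Time to failure (minutes) under constant exposure at ``temperature``.

    Strictly decreasing in temperature; equals ``t_ref`` at ``ctmax``.
    Accepts scalars or arrays.
    """
    temp = _check_temperature(temperature)
    out = params.t_ref * 10.0 ** ((params.ctmax - temp) / params.z)
    return float(out) if np.isscalar(temperature) else out


def tolerated_temperature(params: TDTParams, duration) -> float | np.ndarray:
    """Highest temperature (degrees C) tolerated for ``duration`` minutes.

    Exact inverse of :func:`failure_time`.
    """
    dur = np.asarray(duration, dtype=float)
    if not np.all(np.isfinite(dur) & (dur > 0)):
        raise InvalidInputError("duration must be finite and > 0")
    out = params.ctmax - params.z * np.log10(dur / params.t_ref)
    return float(out) if np.isscalar(duration) else out


def damage_rate(params: TDTParams, temperature) -> float | np.ndarray:
    """Instantaneous damage rate (fraction per minute) at ``temperature``.

    Defined as ``1 / failure_time``, so holding temperature constant for
    exactly the failure time accumulates total damage 1. Strictly
    increasing in temperature; under the log-linear model the proportional
    increase per degree is the constant ``10**(1/z) - 1``.
    """
    temp = _check_temperature(temperature)
    out = 10.0 ** ((temp - params.ctmax) / params.z) / params.t_ref
    return float(out) if np.isscalar(temperature) else out


@dataclass(frozen=True)
class TDTAssay:
    """Static heat-exposure assay records: one failure time per exposure.

    Attributes
    ----------
    temperature : array of float
        Constant exposure temperature of each record (degrees C).
    failure_time : array of float
        Observed time to failure (minutes); all > 0.
    group : array of str, optional
        Individual / stage labels, one per record.
    """

    temperature: np.ndarray
    failure_time: np.ndarray
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        temp = np.asarray(self.temperature, dtype=float)
        ftime = np.asarray(self.failure_time, dtype=float)
        if temp.ndim != 1 or ftime.shape != temp.shape:
            raise InvalidInputError("temperature and failure_time must be equal-length 1-D")
        if temp.size == 0:
            raise InvalidInputError("assay is empty")
        if not np.all(np.isfinite(temp)):
            raise InvalidInputError("assay temperatures must be finite")
        if not np.all(np.isfinite(ftime) & (ftime > 0)):
            raise InvalidInputError("all failure times must be finite and > 0")
        object.__setattr__(self, "temperature", temp)
        object.__setattr__(self, "failure_time", ftime)
        if self.group is not None:
            grp = np.asarray(self.group)
            if grp.shape != temp.shape:
                raise InvalidInputError("group labels must match record count")
            object.__setattr__(self, "group", grp)

    def __len__(self) -> int:
        return self.temperature.size

    def to_frame(self) -> pd.DataFrame:
        data = {"temp_C": self.temperature, "failure_time_min": self.failure_time}
        if self.group is not None:
            data["group"] = self.group
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TDTAssay":
        for col in ("temp_C", "failure_time_min"):
            if col not in frame.columns:
                raise InvalidInputError(f"assay table is missing column {col!r}")
        group = frame["group"].to_numpy() if "group" in frame.columns else None
        return cls(
            temperature=frame["temp_C"].to_numpy(dtype=float),
            failure_time=frame["failure_time_min"].to_numpy(dtype=float),
            group=group,
        )

    @classmethod
    def from_csv(cls, path) -> "TDTAssay":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class TDTFit:
    """Result of fitting a TDT curve to assay data."""

    params: TDTParams
    se_ctmax: float
    se_z: float
    resid_sd: float  # residual sd of log10 failure time (log10 minutes)
    n_obs: int

    def __post_init__(self) -> None:
        if self.se_ctmax < 0 or self.se_z < 0 or self.resid_sd < 0:
            raise InvalidInputError("standard errors must be >= 0")
        if self.n_obs < 2:
            raise InvalidInputError("n_obs must cover the fitted parameters")


def fit_tdt(assay: TDTAssay, t_ref: float = 1.0) -> TDTFit:
    """Fit a TDT curve by OLS of log10(failure_time / t_ref) on temperature.

    The regression ``log10(t/t_ref) = a + b*T`` is converted to the curve
    parameters as ``z = -1/b`` and ``ctmax = -a/b``; their standard errors
    follow by the delta method from the coefficient covariance.

    Raises
    ------
    DegenerateDesignError
        Fewer than 2 distinct exposure temperatures.
    NonTDTBehaviourError
        The fitted slope is >= 0 (failure time does not shorten with
        temperature), which contradicts the model.
    """
    temps = assay.temperature
    if np.unique(temps).size < 2:
        raise DegenerateDesignError(
            "TDT fitting needs at least 2 distinct exposure temperatures"
        )
    y = np.log10(assay.failure_time / t_ref)
    res = sm.OLS(y, sm.add_constant(temps)).fit()
    a, b = res.params
    if b >= 0:
        raise NonTDTBehaviourError(
            f"fitted log10(time) vs temperature slope is {b:.4g} >= 0; "
            "data do not show declining tolerance with temperature"
        )
    z = -1.0 / b
    ctmax = -a / b

    if res.df_resid > 0 and np.isfinite(res.mse_resid):
        cov = np.asarray(res.cov_params())
        # delta method: z = -1/b, ctmax = -a/b
        var_z = cov[1, 1] / b**4
        grad = np.array([-1.0 / b, a / b**2])
        var_ctmax = float(grad @ cov @ grad)
        se_z = float(np.sqrt(max(var_z, 0.0)))
        se_ctmax = float(np.sqrt(max(var_ctmax, 0.0)))
        resid_sd = float(np.sqrt(res.mse_resid))
    else:
        # saturated fit (e.g. exactly 2 points): zero residual, no SE information
        se_z = se_ctmax = resid_sd = 0.0

    return TDTFit(
        params=TDTParams(ctmax=float(ctmax), z=float(z), t_ref=t_ref),
        se_ctmax=se_ctmax,
        se_z=se_z,
        resid_sd=resid_sd,
        n_obs=int(len(assay)),
    )
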