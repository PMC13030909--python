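"""Net damage dynamics and heat-failure probability.

Cumulative heat injury D grows at the TDT damage rate and is offset by a
temperature-dependent repair rate (Arrhenius by default). Below the
calibrated crossover temperature repair outweighs damage (the permissive
range) and injury is repaired; above it damage accumulates, escalating
exponentially with temperature. Failure probability is the clamped damage
p = D in [0, 1], with p = 1 an absorbing (dead) state: no post-failure
repair.

Within one series step the temperature is held constant (left endpoint), so
the per-step update D' = clip(D + net_rate * step) is the exact integral of
the piecewise-constant forcing — finer sub-stepping cannot change it.
Populations are simulated by drawing per-individual TDT parameters from
truncated normals and integrating all individuals vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    CalibrationError,
    ConfigurationError,
    InvalidInputError,
    NoCrossoverError,
)
from .microclimate import MicroclimateSeries
from .tdt import TDTParams, damage_rate

__all__ = [
    "BOLTZMANN_EV_PER_K",
    "RepairParams",
    "StageSpec",
    "Individual",
    "FailureTrajectory",
    "repair_rate",
    "calibrate_repair",
    "net_damage_rate",
    "permissive_boundary",
    "step_damage",
    "simulate_individual",
    "draw_population",
    "simulate_population",
]

#: Boltzmann constant in eV per kelvin, used by the Arrhenius repair shape.
BOLTZMANN_EV_PER_K = 8.617e-5

_MIN_Z = 0.5  # lower truncation for individual thermal sensitivity draws


@dataclass(frozen=True)
class RepairParams:
    """Temperature-dependent repair-rate function.

    ``shape`` selects the functional form:

    * ``"arrhenius"`` — r_ref * exp[(e_a / k_B) * (1/T_ref_K - 1/T_K)],
      rising monotonically with temperature (activation energy ``e_a`` in
      eV, reference temperature ``t_ref_c`` in degrees C).
    * ``"gaussian"`` — r_ref * exp[-0.5 * ((T - t_opt) / sigma)^2], a
      peaked repair capacity with a maximum at ``t_opt``.
    * ``"off"`` — repair rate identically 0.
    """

    shape: str = "arrhenius"
    r_ref: float = 0.0
    e_a: float = 0.65
    t_ref_c: float = 31.0
    t_opt: float = 31.0
    sigma: float = 5.0

    def __post_init__(self) -> None:
        if self.shape not in ("arrhenius", "gaussian", "off"):
            raise InvalidInputError(f"unknown repair shape {self.shape!r}")
        if not (np.isfinite(self.r_ref) and self.r_ref >= 0):
            raise InvalidInputError(f"r_ref must be >= 0, got {self.r_ref!r}")
        if self.shape == "gaussian" and not (np.isfinite(self.sigma) and self.sigma > 0):
            raise InvalidInputError("gaussian repair needs sigma > 0")


def repair_rate(repair: RepairParams, temperature) -> float | np.ndarray:
    """Repair rate (damage fraction per minute) at ``temperature`` (deg C)."""
    temp = np.asarray(temperature, dtype=float)
    if not np.all(np.isfinite(temp)):
        raise InvalidInputError("temperature must be finite")
    if repair.shape == "off":
        out = np.zeros_like(temp)
    elif repair.shape == "arrhenius":
        t_ref_k = repair.t_ref_c + 273.15
        t_k = temp + 273.15
        out = repair.r_ref * np.exp(
            (repair.e_a / BOLTZMANN_EV_PER_K) * (1.0 / t_ref_k - 1.0 / t_k)
        )
    else:  # gaussian
        out = repair.r_ref * np.exp(-0.5 * ((temp - repair.t_opt) / repair.sigma) ** 2)
    return float(out) if out.ndim == 0 else out


def calibrate_repair(
    tdt: TDTParams,
    t_cross: float,
    shape: str = "arrhenius",
    *,
    e_a: float = 0.65,
    t_opt: float | None = None,
    sigma: float = 5.0,
) -> RepairParams:
    """Scale a repair function so it exactly balances damage at ``t_cross``.

    Returns RepairParams with ``repair_rate(t_cross) == damage_rate(t_cross)``
    and the reference temperature anchored at ``t_cross``, making ``t_cross``
    the permissive/stressful boundary by construction.
    """
    if shape == "off":
        raise CalibrationError("cannot calibrate a crossover with repair disabled")
    if not np.isfinite(t_cross):
        raise InvalidInputError("t_cross must be finite")
    target = damage_rate(tdt, t_cross)
    if shape == "arrhenius":
        return RepairParams(shape="arrhenius", r_ref=target, e_a=e_a, t_ref_c=t_cross)
    if shape == "gaussian":
        t_opt = t_cross if t_opt is None else t_opt
        peak = target / np.exp(-0.5 * ((t_cross - t_opt) / sigma) ** 2)
        return RepairParams(shape="gaussian", r_ref=float(peak), t_opt=t_opt, sigma=sigma)
    raise InvalidInputError(f"unknown repair shape {shape!r}")


def net_damage_rate(
    tdt: TDTParams, repair: RepairParams, temperature
) -> float | np.ndarray:
    """Signed net rate: damage_rate - repair_rate (fraction per minute).

    Negative in the permissive range, positive in the stressful range.
    """
    return damage_rate(tdt, temperature) - repair_rate(repair, temperature)


def permissive_boundary(
    tdt: TDTParams,
    repair: RepairParams,
    bracket: tuple[float, float] = (0.0, 60.0),
    tol: float = 1e-6,
) -> float:
    """Permissive/stressful boundary: bisection root of the net damage rate.

    Raises :class:`NoCrossoverError` when the net rate does not change sign
    on the bracket (e.g. repair disabled).
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    f_lo = net_damage_rate(tdt, repair, lo)
    f_hi = net_damage_rate(tdt, repair, hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if np.sign(f_lo) == np.sign(f_hi):
        raise NoCrossoverError(
            f"net damage rate does not change sign on [{lo}, {hi}] "
            f"(f({lo})={f_lo:.3g}, f({hi})={f_hi:.3g})"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid = net_damage_rate(tdt, repair, mid)
        if f_mid == 0.0:
            return mid
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class StageSpec:
    """A life stage: its height, mean TDT curve, individual variation and repair.

    ``repair`` may be given explicitly; otherwise it is calibrated from the
    stage-mean TDT curve so that the net damage rate crosses zero at
    ``t_cross`` (degrees C). All individuals of the stage share the
    resolved repair function.
    """

    name: str
    height_cm: float
    tdt_mean: TDTParams
    sd_ctmax: float = 0.0
    sd_z: float = 0.0
    repair: RepairParams | None = None
    t_cross: float = 31.0
    n_individuals: int = 100

    def __post_init__(self) -> None:
        if not self.name:
            raise InvalidInputError("stage name must be non-empty")
        if not (np.isfinite(self.height_cm) and self.height_cm >= 0):
            raise InvalidInputError(f"height_cm must be >= 0, got {self.height_cm!r}")
        if self.sd_ctmax < 0 or self.sd_z < 0:
            raise InvalidInputError("individual-variation sds must be >= 0")
        if self.n_individuals < 1:
            raise InvalidInputError("n_individuals must be >= 1")

    def resolve_repair(self) -> RepairParams:
        if self.repair is not None:
            return self.repair
        return calibrate_repair(self.tdt_mean, self.t_cross)


@dataclass(frozen=True)
class Individual:
    """One simulated individual: its TDT curve and damage state."""

    stage: str
    tdt: TDTParams
    damage: float = 0.0
    failed: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.damage <= 1.0):
            raise InvalidInputError(f"damage must lie in [0, 1], got {self.damage!r}")
        if self.failed and self.damage < 1.0:
            raise InvalidInputError("failed individuals must carry damage 1")

    @property
    def p(self) -> float:
        """Heat failure probability (= clamped cumulative damage)."""
        return 1.0 if self.failed else self.damage


def step_damage(
    individual: Individual, repair: RepairParams, temperature: float, dt: float
) -> Individual:
    """Advance one individual by ``dt`` minutes at constant ``temperature``.

    D' = clip(D + net_rate * dt, 0, 1); reaching 1 sets the permanent
    ``failed`` flag. Failed individuals pass through unchanged.
    """
    if not (np.isfinite(dt) and dt > 0):
        raise InvalidInputError(f"dt must be > 0 minutes, got {dt!r}")
    if individual.failed:
        return individual
    rate = net_damage_rate(individual.tdt, repair, temperature)
    new_damage = float(np.clip(individual.damage + rate * dt, 0.0, 1.0))
    return replace(individual, damage=new_damage, failed=new_damage >= 1.0)


@dataclass(frozen=True)
class FailureTrajectory:
    """Damage / failure-probability paths for a simulated population.

    ``damage`` has shape (n_times, n_individuals); failure probability is
    the damage itself (clamped to [0, 1] with 1 absorbing), and ``mean_p``
    is the arithmetic mean across individuals at each time.
    """

    times: np.ndarray
    damage: np.ndarray

    def __post_init__(self) -> None:
        dmg = np.asarray(self.damage, dtype=float)
        if dmg.ndim != 2 or dmg.shape[0] != len(self.times):
            raise InvalidInputError("damage must be (n_times, n_individuals)")
        if np.any((dmg < 0) | (dmg > 1)):
            raise InvalidInputError("damage must lie in [0, 1]")
        object.__setattr__(self, "damage", dmg)

    @property
    def p(self) -> np.ndarray:
        """Per-individual failure probability through time."""
        return self.damage

    @property
    def mean_p(self) -> np.ndarray:
        """Population-mean failure probability through time."""
        return self.damage.mean(axis=1)

    @property
    def n_individuals(self) -> int:
        return self.damage.shape[1]

    @property
    def failed(self) -> np.ndarray:
        """Final failed flag per individual."""
        return self.damage[-1] >= 1.0


def _integrate(
    ctmax: np.ndarray,
    z: np.ndarray,
    t_ref: float,
    repair: RepairParams,
    temps: np.ndarray,
    step_minutes: float,
    d0=0.0,
) -> np.ndarray:
    """Exact integration of clip-bounded net damage under piecewise-constant
    temperature; returns damage of shape (n_times, n_individuals)."""
    n = ctmax.size
    m = temps.size
    rep = np.asarray(repair_rate(repair, temps), dtype=float).reshape(m)
    damage = np.empty((m, n))
    d = np.broadcast_to(np.asarray(d0, dtype=float), (n,)).copy()
    d = np.clip(d, 0.0, 1.0)
    damage[0] = d
    for j in range(m - 1):
        # net rate is constant over [t_j, t_{j+1}) -> linear-in-time update
        net = 10.0 ** ((temps[j] - ctmax) / z) / t_ref - rep[j]
        d = np.where(d >= 1.0, 1.0, np.clip(d + net * step_minutes, 0.0, 1.0))
        damage[j + 1] = d
    return damage


def simulate_individual(
    tdt: TDTParams,
    repair: RepairParams,
    series: MicroclimateSeries,
    height_cm: float | None = None,
    dt: float = 1.0,
    d0: float = 0.0,
) -> FailureTrajectory:
    """Integrate one individual's damage along a temperature series.

    ``height_cm`` selects the trace (may be omitted for single-height
    series). ``dt`` is accepted for interface compatibility; because the
    forcing is piecewise constant the per-step update is already exact and
    sub-stepping below the series resolution cannot alter the result.
    """
    if not (np.isfinite(dt) and dt > 0):
        raise InvalidInputError(f"dt must be > 0 minutes, got {dt!r}")
    if height_cm is None:
        if len(series.temps) != 1:
            raise ConfigurationError(
                f"height_cm is required for a multi-height series "
                f"(heights: {series.heights})"
            )
        temps = next(iter(series.temps.values()))
    else:
        temps = series.trace_at(height_cm)
    damage = _integrate(
        np.array([tdt.ctmax]),
        np.array([tdt.z]),
        tdt.t_ref,
        repair,
        temps,
        series.step_minutes,
        d0=d0,
    )
    return FailureTrajectory(times=np.asarray(series.times), damage=damage)


def draw_population(stage: StageSpec, seed: int) -> list[Individual]:
    """Draw ``stage.n_individuals`` individuals with normal variation.

    ctmax_i ~ Normal(mean, sd_ctmax); z_i ~ Normal(mean, sd_z) truncated at
    z >= 0.5 (redrawn below the bound). Deterministic given ``seed``.
    """
    ctmax, z = _draw_parameters(stage, seed)
    return [
        Individual(stage=stage.name, tdt=TDTParams(float(c), float(zi), stage.tdt_mean.t_ref))
        for c, zi in zip(ctmax, z)
    ]


def _draw_parameters(stage: StageSpec, seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    n = stage.n_individuals
    ctmax = rng.normal(stage.tdt_mean.ctmax, stage.sd_ctmax, n)
    z = rng.normal(stage.tdt_mean.z, stage.sd_z, n)
    low = z < _MIN_Z
    while np.any(low):
        z[low] = rng.normal(stage.tdt_mean.z, stage.sd_z, int(low.sum()))
        low = z < _MIN_Z
    return ctmax, z


def simulate_population(
    stage: StageSpec,
    series: MicroclimateSeries,
    dt: float = 1.0,
    seed: int = 0,
) -> FailureTrajectory:
    """Simulate the whole stage population against its height's trace."""
    if not (np.isfinite(dt) and dt > 0):
        raise InvalidInputError(f"dt must be > 0 minutes, got {dt!r}")
    temps = series.trace_at(stage.height_cm)  # ConfigurationError if absent
    ctmax, z = _draw_parameters(stage, seed)
    damage = _integrate(
        ctmax,
        z,
        stage.tdt_mean.t_ref,
        stage.resolve_repair(),
        temps,
        series.step_minutes,
    )
    return FailureTrajectory(times=np.asarray(series.times), damage=damage)
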