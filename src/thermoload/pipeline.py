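"""Config-driven orchestration.

Builds or loads a microclimate series, draws one population per life stage,
integrates damage dynamics at each stage's height and writes per-stage
trajectory CSVs plus a run-level JSON summary. Runs are pure functions of
(config, seed): replaying the same configuration produces byte-identical
outputs. Each stage draws its population from a sub-seed derived by hashing
the master seed with the stage name, so adding a stage never perturbs the
draws of the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .damage import RepairParams, StageSpec, simulate_population
from .errors import ConfigurationError, IntegrityError
from .microclimate import (
    AIR_REFERENCE_HEIGHT_CM,
    MicroclimateSeries,
    ProfileParams,
    apply_profile,
    read_microclimate_csv,
)
from .synthetic import (
    WeatherScenario,
    generate_microclimate,
    load_scenario,
    scenario_from_dict,
    scenario_to_dict,
)
from .tdt import DEFAULT_STAGE_TDT, TDTParams

__all__ = [
    "PipelineConfig",
    "StageSummary",
    "RunSummary",
    "default_stages",
    "config_from_dict",
    "config_to_dict",
    "load_config",
    "stage_seed",
    "run_pipeline",
    "summarize",
]

log = logging.getLogger("thermoload")

#: Default stage heights (cm above soil surface).
DEFAULT_STAGE_HEIGHTS = {"pollen": 50.0, "seed": 0.0, "seedling": 1.0}


def default_stages(n_individuals: int = 100) -> list[StageSpec]:
    """The three default life stages with mild individual variation."""
    return [
        StageSpec(
            name=name,
            height_cm=DEFAULT_STAGE_HEIGHTS[name],
            tdt_mean=DEFAULT_STAGE_TDT[name],
            sd_ctmax=0.5,
            sd_z=0.15,
            n_individuals=n_individuals,
        )
        for name in ("pollen", "seed", "seedling")
    ]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated run configuration.

    The input is either a generative (scenario, profile) pair or a
    microclimate CSV path; exactly one must be set.
    """

    stages: tuple[StageSpec, ...]
    scenario: WeatherScenario | None = None
    profile: ProfileParams | None = None
    microclimate_csv: str | None = None
    dt_minutes: float = 1.0
    seed: int = 0
    out_dir: str = "thermoload_out"
    write_individuals: bool = True
    strict_csv: bool = False

    def __post_init__(self) -> None:
        if not self.stages:
            raise ConfigurationError("at least one stage is required")
        names = [s.name for s in self.stages]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"stage names must be unique, got {names}")
        if self.dt_minutes <= 0:
            raise ConfigurationError("dt_minutes must be > 0")
        has_scenario = self.scenario is not None
        has_csv = self.microclimate_csv is not None
        if has_scenario == has_csv:
            raise ConfigurationError(
                "input: provide exactly one of a weather scenario or a microclimate CSV"
            )
        if has_scenario and self.profile is None:
            object.__setattr__(self, "profile", ProfileParams())


def _err(path: str, message: str) -> ConfigurationError:
    return ConfigurationError(f"{path}: {message}")


def _get_mapping(data, path: str) -> dict:
    if not isinstance(data, dict):
        raise _err(path, f"expected a mapping, got {type(data).__name__}")
    return data


def _parse_stage(data, path: str) -> StageSpec:
    data = _get_mapping(data, path)
    known = {
        "name", "height_cm", "tdt", "sd_ctmax", "sd_z", "repair", "t_cross",
        "n_individuals",
    }
    unknown = set(data) - known
    if unknown:
        raise _err(path, f"unknown field(s) {sorted(unknown)}")
    if "name" not in data:
        raise _err(f"{path}.name", "required")
    name = str(data["name"])

    if "tdt" in data:
        tdt_map = _get_mapping(data["tdt"], f"{path}.tdt")
        try:
            tdt = TDTParams(**tdt_map)
        except TypeError as exc:
            raise _err(f"{path}.tdt", str(exc)) from None
    elif name in DEFAULT_STAGE_TDT:
        tdt = DEFAULT_STAGE_TDT[name]
    else:
        raise _err(f"{path}.tdt", f"required for non-default stage {name!r}")

    if "height_cm" in data:
        height = float(data["height_cm"])
    elif name in DEFAULT_STAGE_HEIGHTS:
        height = DEFAULT_STAGE_HEIGHTS[name]
    else:
        raise _err(f"{path}.height_cm", f"required for non-default stage {name!r}")

    repair = None
    if "repair" in data:
        rep_map = _get_mapping(data["repair"], f"{path}.repair")
        try:
            repair = RepairParams(**rep_map)
        except TypeError as exc:
            raise _err(f"{path}.repair", str(exc)) from None
    try:
        return StageSpec(
            name=name,
            height_cm=height,
            tdt_mean=tdt,
            sd_ctmax=float(data.get("sd_ctmax", 0.5)),
            sd_z=float(data.get("sd_z", 0.15)),
            repair=repair,
            t_cross=float(data.get("t_cross", 31.0)),
            n_individuals=int(data.get("n_individuals", 100)),
        )
    except (TypeError, ValueError) as exc:
        raise _err(path, str(exc)) from None


def config_from_dict(data: dict) -> PipelineConfig:
    """Build and validate a config from a YAML-style mapping.

    Errors carry the offending field path (e.g. ``stages[1].height_cm``).
    """
    data = _get_mapping(data, "config")
    known = {
        "stages", "input", "dt_minutes", "seed", "out_dir",
        "write_individuals", "strict_csv",
    }
    unknown = set(data) - known
    if unknown:
        raise _err("config", f"unknown field(s) {sorted(unknown)}")

    if "stages" in data:
        raw_stages = data["stages"]
        if not isinstance(raw_stages, list):
            raise _err("stages", "expected a list of stage mappings")
        stages = tuple(
            _parse_stage(s, f"stages[{i}]") for i, s in enumerate(raw_stages)
        )
    else:
        stages = tuple(default_stages())

    scenario = profile = csv_path = None
    if "input" not in data:
        raise _err("input", "required (scenario/fixture or csv)")
    inp = _get_mapping(data["input"], "input")
    unknown = set(inp) - {"scenario", "fixture", "profile", "csv"}
    if unknown:
        raise _err("input", f"unknown field(s) {sorted(unknown)}")
    sources = [k for k in ("scenario", "fixture", "csv") if k in inp]
    if len(sources) != 1:
        raise _err("input", f"exactly one of scenario/fixture/csv required, got {sources}")
    if "scenario" in inp:
        scenario = scenario_from_dict(_get_mapping(inp["scenario"], "input.scenario"))
    elif "fixture" in inp:
        scenario = load_scenario(str(inp["fixture"]))
    else:
        csv_path = str(inp["csv"])
    if "profile" in inp:
        prof_map = _get_mapping(inp["profile"], "input.profile")
        try:
            profile = ProfileParams(**prof_map)
        except (TypeError, ValueError) as exc:
            raise _err("input.profile", str(exc)) from None

    try:
        return PipelineConfig(
            stages=stages,
            scenario=scenario,
            profile=profile,
            microclimate_csv=csv_path,
            dt_minutes=float(data.get("dt_minutes", 1.0)),
            seed=int(data.get("seed", 0)),
            out_dir=str(data.get("out_dir", "thermoload_out")),
            write_individuals=bool(data.get("write_individuals", True)),
            strict_csv=bool(data.get("strict_csv", False)),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigurationError):
            raise
        raise _err("config", str(exc)) from None


def config_to_dict(config: PipelineConfig) -> dict:
    """Resolved-config mapping suitable for YAML audit dumps."""
    stages = []
    for s in config.stages:
        entry: dict = {
            "name": s.name,
            "height_cm": s.height_cm,
            "tdt": {"ctmax": s.tdt_mean.ctmax, "z": s.tdt_mean.z, "t_ref": s.tdt_mean.t_ref},
            "sd_ctmax": s.sd_ctmax,
            "sd_z": s.sd_z,
            "n_individuals": s.n_individuals,
        }
        if s.repair is not None:
            rep = s.repair
            entry["repair"] = {
                "shape": rep.shape, "r_ref": rep.r_ref, "e_a": rep.e_a,
                "t_ref_c": rep.t_ref_c, "t_opt": rep.t_opt, "sigma": rep.sigma,
            }
        else:
            entry["t_cross"] = s.t_cross
        stages.append(entry)
    if config.scenario is not None:
        prof = config.profile
        inp = {
            "scenario": scenario_to_dict(config.scenario),
            "profile": {
                "a0": prof.a0,
                "h_scale": prof.h_scale,
                "night_deficit": prof.night_deficit,
                "shade_fraction": prof.shade_fraction,
            },
        }
    else:
        inp = {"csv": config.microclimate_csv}
    return {
        "stages": stages,
        "input": inp,
        "dt_minutes": config.dt_minutes,
        "seed": config.seed,
        "out_dir": config.out_dir,
        "write_individuals": config.write_individuals,
        "strict_csv": config.strict_csv,
    }


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)


def stage_seed(master_seed: int, stage_name: str) -> int:
    """Deterministic per-stage sub-seed, stable across runs and platforms."""
    digest = hashlib.sha256(f"{master_seed}:{stage_name}".encode()).digest()
    return int.from_bytes(digest[:8], "little")


@dataclass(frozen=True)
class StageSummary:
    height_cm: float
    final_mean_p: float
    fraction_failed: float | None
    first_failure_time: str | None  # ISO timestamp of first individual failure
    peak_temp_c: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.final_mean_p <= 1.0):
            raise IntegrityError("final_mean_p outside [0, 1]")
        if self.fraction_failed is not None and not (0.0 <= self.fraction_failed <= 1.0):
            raise IntegrityError("fraction_failed outside [0, 1]")


@dataclass(frozen=True)
class RunSummary:
    """Per-stage endpoints plus per-height temperature extremes."""

    stages: dict[str, StageSummary]
    heights: dict[float, dict[str, float]]

    def to_dict(self) -> dict:
        return {
            "stages": {
                name: {
                    "height_cm": s.height_cm,
                    "final_mean_p": s.final_mean_p,
                    "fraction_failed": s.fraction_failed,
                    "first_failure_time": s.first_failure_time,
                    "peak_temp_c": s.peak_temp_c,
                }
                for name, s in sorted(self.stages.items())
            },
            "heights": {
                f"{h:g}": dict(sorted(v.items()))
                for h, v in sorted(self.heights.items())
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunSummary":
        return cls(
            stages={
                name: StageSummary(**entry) for name, entry in data["stages"].items()
            },
            heights={float(h): dict(v) for h, v in data["heights"].items()},
        )

    def __eq__(self, other) -> bool:
        return isinstance(other, RunSummary) and self.to_dict() == other.to_dict()


def _individual_columns(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"p_{i + 1:0{width}d}" for i in range(n)]


def _build_series(config: PipelineConfig) -> MicroclimateSeries:
    needed = sorted({s.height_cm for s in config.stages})
    if config.scenario is not None:
        return generate_microclimate(config.scenario, config.profile, needed)
    series = read_microclimate_csv(config.microclimate_csv, strict=config.strict_csv)
    missing = [h for h in needed if not series.has_height(h)]
    if not missing:
        return series
    if (
        config.profile is not None
        and series.has_height(AIR_REFERENCE_HEIGHT_CM)
        and series.solar is not None
        and series.dryness is not None
    ):
        return apply_profile(series, config.profile, needed)
    raise ConfigurationError(
        f"microclimate input lacks stage height(s) {missing}; "
        f"available heights: {series.heights}"
    )


def _summarize_stage_frame(frame: pd.DataFrame, source: str) -> tuple[str, StageSummary]:
    required = {"datetime", "stage", "height_cm", "temp_C", "mean_p"}
    missing = required - set(frame.columns)
    if missing:
        raise IntegrityError(f"{source}: missing column(s) {sorted(missing)}")
    if frame.empty:
        raise IntegrityError(f"{source}: empty trajectory")
    names = frame["stage"].unique()
    if len(names) != 1:
        raise IntegrityError(f"{source}: expected one stage per file, got {list(names)}")
    name = str(names[0])
    p_cols = [c for c in frame.columns if c.startswith("p_")]
    if p_cols:
        p = frame[p_cols].to_numpy(dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise IntegrityError(f"{source}: probabilities outside [0, 1]")
        failed = p[-1] >= 1.0
        fraction_failed = float(failed.mean())
        any_failed = (p >= 1.0).any(axis=1)
        if any_failed.any():
            idx = int(np.argmax(any_failed))
            first_failure = pd.Timestamp(frame["datetime"].iloc[idx]).isoformat()
        else:
            first_failure = None
    else:
        fraction_failed = None
        first_failure = None
    return name, StageSummary(
        height_cm=float(frame["height_cm"].iloc[0]),
        final_mean_p=float(frame["mean_p"].iloc[-1]),
        fraction_failed=fraction_failed,
        first_failure_time=first_failure,
        peak_temp_c=float(frame["temp_C"].max()),
    )


def run_pipeline(config: PipelineConfig) -> RunSummary:
    """Execute the full run and write outputs to ``config.out_dir``.

    Outputs: one ``trajectory_<stage>.csv`` per stage, ``summary.json`` and
    the resolved ``config.yaml``. Returns the run summary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series = _build_series(config)
    log.info(
        "simulating %d stage(s) over %d steps at %d height(s)",
        len(config.stages), len(series), len(series.temps),
    )

    stage_frames: list[pd.DataFrame] = []
    for stage in config.stages:
        sub_seed = stage_seed(config.seed, stage.name)
        traj = simulate_population(stage, series, dt=config.dt_minutes, seed=sub_seed)
        log.debug(
            "stage %s: final mean p %.4f, %d/%d failed",
            stage.name, traj.mean_p[-1], int(traj.failed.sum()), traj.n_individuals,
        )
        data = {
            "datetime": series.times.strftime("%Y-%m-%dT%H:%M:%S"),
            "stage": stage.name,
            "height_cm": stage.height_cm,
            "temp_C": series.trace_at(stage.height_cm),
            "mean_p": traj.mean_p,
        }
        frame = pd.DataFrame(data)
        if config.write_individuals:
            cols = _individual_columns(traj.n_individuals)
            frame = pd.concat(
                [frame, pd.DataFrame(traj.p, columns=cols, index=frame.index)], axis=1
            )
        frame.to_csv(out / f"trajectory_{stage.name}.csv", index=False)
        stage_frames.append(frame)

    stages: dict[str, StageSummary] = {}
    heights: dict[float, dict[str, float]] = {}
    for frame in stage_frames:
        name, summary = _summarize_stage_frame(frame, f"stage {frame['stage'].iloc[0]}")
        stages[name] = summary
        heights[summary.height_cm] = {
            "max_temp_c": float(frame["temp_C"].max()),
            "min_temp_c": float(frame["temp_C"].min()),
        }
    run_summary = RunSummary(stages=stages, heights=heights)

    with open(out / "summary.json", "w") as fh:
        json.dump(run_summary.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)
    return run_summary


def summarize(out_dir) -> RunSummary:
    """Recompute the run summary from emitted trajectory CSVs only.

    Consistency contract: for a completed run this reproduces the summary
    written by :func:`run_pipeline` exactly.
    """
    out = Path(out_dir)
    paths = sorted(out.glob("trajectory_*.csv"))
    if not paths:
        raise IntegrityError(f"no trajectory_*.csv files found in {out}")
    stages: dict[str, StageSummary] = {}
    heights: dict[float, dict[str, float]] = {}
    for path in paths:
        try:
            frame = pd.read_csv(path, float_precision="round_trip")
        except Exception as exc:  # noqa: BLE001 - surface as integrity problem
            raise IntegrityError(f"{path}: unreadable trajectory ({exc})") from exc
        name, summary = _summarize_stage_frame(frame, str(path))
        if name in stages:
            raise IntegrityError(f"{path}: duplicate stage {name!r}")
        stages[name] = summary
        heights[summary.height_cm] = {
            "max_temp_c": float(frame["temp_C"].max()),
            "min_temp_c": float(frame["temp_C"].min()),
        }
    return RunSummary(stages=stages, heights=heights)
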