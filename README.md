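# thermoload

Thermal load sensitivity simulations for vulnerable plant life stages:
thermal death time (TDT) curves, cumulative heat-injury dynamics with
Arrhenius repair, and heat-failure probability for simulated individuals and
populations exposed to height-stratified microclimate temperature series.

## What it does

- **`thermoload.tdt`** — TDT curves `t_fail(T) = t_ref · 10^((ctmax − T)/z)`:
  evaluation in both directions, the derived instantaneous damage rate
  (`1 / t_fail`), and OLS fitting of log10 failure time on temperature from
  static assay tables, with delta-method standard errors.
- **`thermoload.damage`** — net damage = damage − repair. Repair is an
  Arrhenius exponential (Gaussian-peak and off variants included),
  calibrated so repair exactly balances damage at a crossover temperature
  (31 °C by default). Below the crossover (permissive range) injury is
  repaired; above it (stressful range) damage accumulates, escalating more
  than 100 % per +1 °C. Failure probability is the clamped damage
  `p = D ∈ [0, 1]` with `p = 1` absorbing (no post-failure repair).
  Populations draw per-individual `ctmax` and `z` from truncated normals.
- **`thermoload.microclimate`** — uniform-step temperature traces keyed by
  height above soil. A simple exponential-decay excess profile maps the
  1.2 m air trace to near-surface heights; defaults are calibrated so a
  clear dry unshaded day peaks +20 °C at the surface and +8 °C at 1 cm.
  Long-format CSV I/O with strict/sorting modes.
- **`thermoload.synthetic`** — deterministic weather generator (diurnal
  half-sine days, linear night cooling, heatwave pulses, rain days with
  linear dryness recovery) and TDT assay generators with log10-normal noise
  for parameter-recovery tests. Fixture scenarios ship with the package.
- **`thermoload.pipeline`** — YAML-config-driven orchestration: build or
  load the series, simulate each stage's population at its height (pollen
  50 cm, seedling 1 cm, imbibed seed 0 cm by default, n = 100 each), write
  per-stage trajectory CSVs, a JSON summary and the resolved config.
  Runs are byte-identical given (config, seed); each stage derives its
  sub-seed by hashing the master seed with the stage name.

## CLI

```sh
# full run from a config file (exit code 2 on validation errors)
thermoload run --config config.yaml --out outdir --seed 1

# synthetic 1.2 m air series from a scenario YAML
thermoload weather --scenario scenario.yaml --out weather.csv

# fit a TDT curve to an assay CSV (columns: temp_C, failure_time_min)
thermoload fit-tdt assay.csv --json

# one stage against an existing microclimate CSV
thermoload simulate --microclimate weather.csv --stage stage.yaml --out traj.csv
```

Example run config:

```yaml
seed: 1
dt_minutes: 1.0
write_individuals: true        # include p_001..p_n columns in trajectories
input:
  fixture: scenario_heatwave_10day   # or scenario: {...}, or csv: path.csv
  # profile: {a0: 20.0, night_deficit: 2.0, shade_fraction: 0.0}
stages:                        # omit entirely to get the three defaults
  - name: pollen               # default height 50 cm, ctmax 46, z 3.0
    n_individuals: 100
    sd_ctmax: 0.5
    sd_z: 0.15
    t_cross: 31.0              # repair calibrated here, or repair: {...}
  - name: seed                 # 0 cm, ctmax 58, z 4.5
  - name: seedling             # 1 cm, ctmax 52, z 3.5
```

Scenario YAML fields mirror `WeatherScenario`: `n_days`, `tmin`, `tmax`
(scalars or per-day lists), `heatwave_days`, `tmax_boost`, `rain_days`,
`daylength_hours`, `peak_hour`, `dryness_recovery_days`, `step_minutes`,
`start`, `seed`. Two fixtures are bundled: `scenario_heatwave_10day`
(two heatwave pulses separated by a rain day) and `scenario_benign`
(permissive everywhere).

Microclimate CSV format: columns `datetime` (ISO 8601), `height_cm`,
`temp_C`, optional `solar`, `dryness`, `rain`; one row per (height, time).

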