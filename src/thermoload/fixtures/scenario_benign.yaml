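# Cool, uneventful days: even the soil surface stays below the default
# 31 degree permissive/stressful boundary, so no damage ever accrues.
n_days: 5
tmin: 2.0
tmax: 6.0
heatwave_days: []
tmax_boost: 12.0
rain_days: []
daylength_hours: 14.0
peak_hour: 14.0
dryness_recovery_days: 2.0
step_minutes: 10.0
start: "2024-01-01"
seed: 0
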