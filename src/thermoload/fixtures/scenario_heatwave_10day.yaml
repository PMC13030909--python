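# Ten summer days with a mid-period two-day heatwave, a rain day that
# allows overnight repair, and a second late heatwave that re-tests the
# partially damaged population.
n_days: 10
tmin: 16.0
tmax: 26.0
heatwave_days: [3, 4, 8, 9]
tmax_boost: 12.0
rain_days: [5]
daylength_hours: 14.0
peak_hour: 14.0
dryness_recovery_days: 2.0
step_minutes: 10.0
start: "2024-01-01"
seed: 0
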