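kind: season_spec
name: season_2023like
planting_date: 2023-05-10
n_days: 135
latitude: 43.35
elevation_m: 290.0
target_rain_mm: 312.8
seed: 2023
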