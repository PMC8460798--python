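# End-to-end run config for `emerge run --config examples/run.yaml`.
# Exactly one input source: a simulation block, or weather_csv +
# emergence_csv + season_year.
simulation:
  seed: 17
  n_sites: 2
  seedbank_n: 10000
base_temp: 21.0
direction: below_base
early_season_ceiling: 0.5
window_weeks: 4
span_weeks: 4
out_dir: scratch/run_from_yaml
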