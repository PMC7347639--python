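# Example pipeline configuration (synthetic mode).
# For real CSV inputs, replace `synthetic` with pollen_csv / search_csv /
# station_meta_csv / region_meta_csv paths.
synthetic:
  n_site_years: 30
  year: 2015
  censor_tv_homes_ref: 300000.0   # small markets censor more days
  pollen:
    noise_cv: 0.4
  missingness:
    weekend_missing_prob: 0.7
    edge_gap_days: [3, 7]
seed: 9
outdir: scratch_run
thresholds:
  max_pct_missing: 60.0
  max_gap_near_high: 4
  high_threshold: 200.0
transform:
  log_offset: 1.0
  lowess_light_bw: 0.1
  lowess_heavy_bw: 0.8
start_definition:
  method: cumulative_fraction
  fraction: 0.05
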