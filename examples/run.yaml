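# Demo pipeline configuration: simulate a 5-trait panel with three planted
# clusters of causal variants, then run the full analysis.
seed: 5
simulate:
  K: 5
  n_regions: 150
  snps_per_region: 25
  n_causal: 120
  k_clusters: 3
  missing_rate: 0.1
  effect_scale: 4.0
covariance:
  method: trimmed
  trim_p: 5.0e-8
impute:
  lambda: 0.1
  quality_threshold: 0.6
tests:
  threshold: 1.0e-8
cluster:
  k_range: [2, 4]
  n_boot: 6
  min_snps: 15
  entropy_threshold: 0.75
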