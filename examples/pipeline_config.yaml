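# Demo configuration for `hsiph run --config examples/pipeline_config.yaml`.
# Any key may be omitted; defaults reproduce the reference experiment's
# geometry (33 sausages x 5 regions = 165 rows, 110/55 split).
out_dir: pipeline_out
seed: 1
grid: {start_nm: 350, stop_nm: 1100, step_nm: 5}
simulate:
  n_samples: 33
  shape: [48, 72]
  noise_sd: 0.003
  gain_sd: 0.03
  offset_sd: 0.01
  ph_range: [4.44, 6.46]
segmentation: {band_index: 70, threshold: 0.075, k_regions: 5}
# fraction just under 2/3 so ceil(fraction * 165) = 110, as exact 2/3 gives
split: {fraction: 0.66666666, by_sample: false}
model: {n_latent: 8, cv_scheme: kfold, cv_k: 10}
chains:
  - Raw
  - 1st Derivative
  - 2nd Derivative
  - MSC
  - SNV
  - Normalization
  - Normalization + 1st Derivative
  - 1st Derivative + Normalization
  - Normalization + 2nd Derivative
  - 2nd Derivative + Normalization
feature_selection: {k: 12, min_separation_bands: 2, preset: false, source_chain: Raw}
map: {scale: [4.4, 6.5], palette: jet}
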