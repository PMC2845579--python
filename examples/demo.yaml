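# Demo pipeline configuration: a small 3-subject phantom cohort.
# Run with: cmrquant run --config examples/demo.yaml --out demo_run/
phantom:
  seed: 7
  n_subjects: 3
  n_frames: 40
  frame_interval_s: 1.0
  grid_shape: [24, 24]
  n_slices: 3
  noise_sd: 0.0
  targeted_territory: LAD
k_total: 2.0
k_core: 3.0
density_g_per_ml: 1.05
alpha: 0.05
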