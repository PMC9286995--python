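# Minimal end-to-end configuration: small phantom frames whose 64 px ROI
# stands in for the 128 px ROI used on full-size acquisitions.
out_dir: runs/demo
seed: 0
n_train_cases: 2
n_val_cases: 1
n_test_cases: 2
roi_size: 64
roi_k: 3
gap_mm: 0.0
phantom:
  image_size: 96
  pixel_spacing_mm: 1.367
  slice_thickness_mm: 8.0
  n_slices: null
  n_slices_range: [6, 12]
  endo_radius_px: [10.0, 16.0]
  wall_thickness_px: [4.0, 7.0]
  es_scale: 0.65
  intensity_pool: 400.0
  intensity_myo: 180.0
  intensity_bg: 60.0
  noise_sd: 12.0
  center_jitter_px: 6.0
  apex_taper: 0.93
  wobble_amp_px: 1.0
  wobble_lobes: 5
  seed: 0
arch:
  input_size: 64
  in_channels: 1
  n_classes: 2
  n_levels: 3
  base_channels: 8
  use_medium_skip: true
  use_short_skip: true
  conv_type: depthwise_separable
  downsample: pooling
  seed: 0
train:
  lr_initial: 0.001
  lr_final: 0.0001
  lr_end_epoch: 12
  n_epochs: 12
  batch_size: 16
  loss: cross_entropy
  optimizer: adam
  seed: 0
  target: endo
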