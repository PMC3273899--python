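# End-to-end demo: two simulated populations, full pipeline, classification.
#   lamina run --config examples/demo_config.yaml --out results/demo
seed: 1
jitter: 0.1
shape: [128, 128, 128]
spacing_nm: [50.0, 50.0, 50.0]
populations:
  fresh:
    template: fresh
    n: 15
  senescent:
    template: senescent
    n: 15
microscope:
  psf_sigma_nm: [250.0, 100.0, 100.0]
  photon_scale: 1.0
  read_noise_sd: 2.0
  background: 5.0
segmentation:
  smoothing_sigma_nm: 100.0
  threshold_method: multiotsu
  min_volume_um3: 5.0       # simulated nuclei are ~half real linear scale
  mesh_step_size: 1
features:
  neighborhood_scale: 3.0
  smooth_iterations: 10
  max_curvature_vertices: 8000
classification:
  feature_subset: [intensity, skewness, curvature]
  n_perm: 199
  standardize: true
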