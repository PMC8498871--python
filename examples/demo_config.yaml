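# End-to-end synthetic demo: run with
#   monolayer-mech run --config examples/demo_config.yaml --out demo_out
# Re-running with the same seed reproduces bit-identical outputs
# (see demo_out/manifest.json checksums).
seed: 123
stages:
  - stage: simulate_field
    shape: [64, 64]
    xi_um: 30
    sigma: 5
    drift: [10, 0]
    n_frames: 3
  - stage: velocimetry
  - stage: simulate_tracks
    n: 50
    n_frames: 60
    model: brownian
    D_um2_per_min: 1.0
    dt_min: 7.5
    box_um: 2000
  - stage: msd
    dt_min: 7.5
    fit_hi_min: 120.0
  - stage: simulate_tessellation
    n_cells: 150
    frame_shape: [256, 256]
    mean_area_um2: 300
    skew_target: 2.0
  - stage: morphometry
  - stage: simulate_force_curve
    preset: wt
    noise_rel: 0.01
  - stage: mech_fit
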