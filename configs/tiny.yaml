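# Minimal smoke configuration: a 3-day colony, coarse voxels, < 1 min.
generator:
  n_initial_hyphae: 4
  duration_hours: 72.0
  snapshot_hours: [24.0, 48.0, 72.0]
  lag_hours: 24.0
  max_tips: 80
biomass:
  voxel_xy_um: 40.0
  voxel_z_um: 40.0
  stack_depth_um: 80.0
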