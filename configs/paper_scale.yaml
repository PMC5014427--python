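# Full 17-day run with the default (tabulated) growth statistics and the
# observation days 3, 4, 5, 7, 10, 12, 14 and 17.  The tip cap keeps the
# exponential phase computable; raise max_tips for larger colonies.
generator:
  n_initial_hyphae: 5
  duration_hours: 408.0
  snapshot_hours: [72.0, 96.0, 120.0, 168.0, 240.0, 288.0, 336.0, 408.0]
  lag_hours: 120.0
  max_tips: 600
biomass:
  voxel_xy_um: 20.0
  voxel_z_um: 20.0
  stack_depth_um: 200.0
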