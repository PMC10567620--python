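name: uexplorer_sparse_bgo_194
family: radial-crystal
catalog_afov_cm: 194.8
crystal:
  material: BGO
  n_units: 29
  unit_axial_length_cm: 6.717241
  inter_unit_gap_cm: 0.0
  n_blocks_per_ring: 24
  crystals_per_block_transaxial: 35
  crystals_per_block_axial: 24
  crystal_transaxial_cm: 0.276
  crystal_axial_cm: 0.276
  crystal_depth_cm: 1.81
  ring_inner_radius_cm: 39.3
  sparse_units: alternate
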