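name: uexplorer_full_bgo_194
family: radial-crystal
catalog_afov_cm: 194.8
crystal:
  material: BGO
  n_units: 8
  unit_axial_length_cm: 24.35
  inter_unit_gap_cm: 0.0
  n_blocks_per_ring: 24
  crystals_per_block_transaxial: 35
  crystals_per_block_axial: 84
  crystal_transaxial_cm: 0.276
  crystal_axial_cm: 0.276
  crystal_depth_cm: 1.81
  ring_inner_radius_cm: 39.3
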