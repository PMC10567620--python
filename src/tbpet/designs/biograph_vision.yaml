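name: biograph_vision
family: radial-crystal
catalog_afov_cm: 26.3
crystal:
  material: LSO
  n_units: 8
  unit_axial_length_cm: 3.2
  inter_unit_gap_cm: 0.1
  n_blocks_per_ring: 38
  crystals_per_block_transaxial: 20
  crystals_per_block_axial: 10
  crystal_transaxial_cm: 0.32
  crystal_axial_cm: 0.32
  crystal_depth_cm: 2.0
  ring_inner_radius_cm: 39.3
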