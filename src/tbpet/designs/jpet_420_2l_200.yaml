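name: jpet_420_2l_200
family: axial-strip
catalog_afov_cm: 200.0
strip:
  material: plastic
  n_layers: 2
  strip_length_cm: 200.0
  strip_width_cm: 0.4
  strip_thickness_cm: 2.0
  innermost_radius_cm: 41.5
  layer_gap_cm: 0.5
  wls: true
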