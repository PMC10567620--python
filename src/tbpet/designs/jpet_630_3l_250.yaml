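name: jpet_630_3l_250
family: axial-strip
catalog_afov_cm: 250.0
strip:
  material: plastic
  n_layers: 3
  strip_length_cm: 250.0
  strip_width_cm: 0.6
  strip_thickness_cm: 3.0
  innermost_radius_cm: 41.5
  layer_gap_cm: 0.5
  wls: true
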