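kind: soil_profile
site: Montcalm
layers:
- top: 0.0
  bottom: 0.15
  texture: sandy loam
  bulk_density: 1.471
- top: 0.15
  bottom: 0.3
  texture: sandy loam
  bulk_density: 1.255
- top: 0.3
  bottom: 0.45
  texture: sandy loam
  bulk_density: 1.369
extend_to: 0.6
dz: 0.05
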