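kind: soil_profile
site: Mecosta
layers:
- top: 0.0
  bottom: 0.15
  texture: loamy sand
  bulk_density: 1.564
- top: 0.15
  bottom: 0.3
  texture: loamy sand
  bulk_density: 1.578
- top: 0.3
  bottom: 0.45
  texture: loamy sand
  bulk_density: 1.6
extend_to: 0.6
dz: 0.05
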