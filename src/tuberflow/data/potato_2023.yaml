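kind: crop_params
name: potato_2023
cc0: 0.6
ccx: 92.0
cgc: 0.018
cdc: 0.8
t_base: 2.0
t_upper: 26.0
zr_min: 0.15
zr_max: 0.47
kctr: 1.1
hi0: 0.75
wp: 19.0
extraction_pattern:
- 0.4
- 0.3
- 0.2
- 0.1
p_exp_upper: 0.26
p_exp_lower: 0.66
p_sto_upper: 0.65
p_sen_upper: 0.69
shape_exp: 3.0
shape_sto: 3.0
shape_sen: 3.0
ks_cold: 1.0
f_hi: 1.0
ke_max: 1.1
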