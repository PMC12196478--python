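# Human tissue:plasma partition coefficients (steady-state ratios), the
# calibrated human column of the reference partition table.
species: human
source: reference
kp:
  lung: 0.32
  adipose: 0.07
  muscle: 0.24
  liver: 2.03
  spleen: 0.06
  heart: 0.29
  brain: 0.24
  kidney: 2.43
  skin: 0.23
  reproductive: 0.36
  red_marrow: 0.20
  yellow_marrow: 0.07
  rest_of_body: 0.28
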