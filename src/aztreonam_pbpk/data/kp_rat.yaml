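# Calibrated rat tissue:plasma partition coefficients (steady-state ratios).
# These are the model's authoritative defaults: single-parameter
# Rodgers-Rowland predictions calibrated against in-vivo tissue data for
# kidney, liver, lung and spleen. The de-novo prediction pathway lives in
# aztreonam_pbpk.partition.
species: rat
source: reference
kp:
  lung: 0.40
  adipose: 0.09
  muscle: 0.29
  liver: 2.5
  spleen: 0.08
  heart: 0.36
  brain: 0.30
  kidney: 3.0
  skin: 0.28
  reproductive: 0.44
  red_marrow: 0.25
  yellow_marrow: 0.09
  rest_of_body: 0.34
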