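# Species clearance defaults. `cl_total` is the final calibrated total plasma
# clearance per species (L/h), the value each species model was conditioned on;
# the mechanistic split (renal = f_up x GFR, remainder hepatic with a 10%
# biliary fraction) is rebuilt from it at load time.
biliary_fraction: 0.10
allometric_exponent: 0.75      # midpoint of the conventional 0.6-0.8 band
cl_total_L_per_h:
  rat: 0.216
  mouse: 0.016
  human: 6.56
  dog: 5.570
  monkey: 0.775
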