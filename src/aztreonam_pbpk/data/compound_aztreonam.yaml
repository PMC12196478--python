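# Aztreonam physicochemical and binding constants (QSAR-predicted inputs used by
# the whole-body model; per-species plasma binding and blood:plasma ratios).
# Dog and monkey plasma binding was never measured for this programme; the rat
# values are adopted for both, as is standard when rodent data are the only
# in-vivo anchor. Override via `overrides=` at load time.
name: aztreonam
molecular_weight: 435.43        # g/mol
log_p: -1.141                   # octanol-water, neutral species
log_d_74: -1.14                 # distribution coefficient at pH 7.4
solubility_74: 1.187            # mg/mL at pH 7.4
pka_values:                     # dominant ionisable group is the acidic pKa 4.09;
  - {value: 4.09, kind: acid}   # the negative entries are groups that are never
  - {value: -0.56, kind: base}  # protonated at physiological pH
  - {value: -5.27, kind: base}
f_up:                           # fraction unbound in plasma
  human: 0.594
  rat: 0.32568
  mouse: 0.47787
  dog: 0.32568                  # adopted from rat (unmeasured)
  monkey: 0.32568               # adopted from rat (unmeasured)
r_bp:                           # blood:plasma concentration ratio
  human: 0.997
  rat: 0.65
  mouse: 0.827
  dog: 0.65                     # adopted from rat (unmeasured)
  monkey: 0.65                  # adopted from rat (unmeasured)
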