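# Cynomolgus monkey 20 mg/kg study; the reported route is ambiguous, the
# default is IV bolus (switch the route to `depot` for the IM interpretation).
name: monkey_20mgkg
species: monkey
regimen: {route: iv_bolus, dose_mg_per_kg: 20}
clearance: calibrated
kp_source: scaled_from_rat
t_end_h: 24
output_resolution_h: 0.01
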