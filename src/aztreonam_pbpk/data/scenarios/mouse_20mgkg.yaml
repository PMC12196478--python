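# Mouse 20 mg/kg subcutaneous study (first-order depot, F = 1).
name: mouse_20mgkg
species: mouse
regimen: {route: depot, dose_mg_per_kg: 20, ka_per_h: 6.0}
clearance: calibrated
kp_source: scaled_from_rat
t_end_h: 24
output_resolution_h: 0.01
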