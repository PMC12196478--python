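# Rat single IV bolus study: 50 mg/kg, destructive sampling over 24 h.
name: rat_50mgkg
species: rat
regimen: {route: iv_bolus, dose_mg_per_kg: 50}
clearance: calibrated
kp_source: reference
t_end_h: 24
output_resolution_h: 0.01
sampling_times_h: [0.25, 0.5, 1, 2, 4, 7, 10, 24]
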