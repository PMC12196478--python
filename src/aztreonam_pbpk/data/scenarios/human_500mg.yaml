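# Human 500 mg dose given as a 2-minute intravenous infusion.
name: human_500mg
species: human
regimen: {route: iv_infusion, dose_mg: 500, infusion_duration_h: 0.03333333333333333}
clearance: calibrated
kp_source: reference
t_end_h: 48
output_resolution_h: 0.005
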