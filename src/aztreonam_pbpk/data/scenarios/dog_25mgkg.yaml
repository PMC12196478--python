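# Dog 25 mg/kg single IV bolus; dog muscle Kp carries the +30% adjustment.
name: dog_25mgkg
species: dog
regimen: {route: iv_bolus, dose_mg_per_kg: 25}
clearance: calibrated
kp_source: scaled_from_rat
t_end_h: 48
output_resolution_h: 0.01
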