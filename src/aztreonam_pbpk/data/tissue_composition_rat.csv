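# Fractional rat tissue composition for the Rodgers-Rowland single-parameter
# partition calculation: extracellular water (f_ew), intracellular water (f_iw),
# neutral lipids (f_nl), neutral phospholipids (f_np) and tissue:plasma albumin
# ratio (albumin_ratio). Standard values from the published tissue-composition
# literature behind the Rodgers-Rowland method; yellow marrow uses the
# adipose-like composition and rest_of_body a whole-body average.
tissue,f_ew,f_iw,f_nl,f_np,albumin_ratio
lung,0.336,0.446,0.022,0.0128,0.212
adipose,0.135,0.017,0.853,0.0016,0.049
muscle,0.118,0.630,0.010,0.0072,0.064
liver,0.161,0.573,0.014,0.0240,0.086
spleen,0.207,0.579,0.0077,0.0113,0.097
heart,0.320,0.456,0.014,0.0111,0.157
brain,0.162,0.620,0.039,0.0015,0.048
kidney,0.273,0.483,0.012,0.0240,0.130
skin,0.382,0.291,0.060,0.0044,0.277
reproductive,0.455,0.399,0.017,0.0030,0.110
red_marrow,0.100,0.346,0.017,0.0017,0.100
yellow_marrow,0.135,0.017,0.853,0.0016,0.049
rest_of_body,0.300,0.450,0.040,0.0060,0.100
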