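# Cynomolgus monkey whole-body physiology: compartment volumes (mL) and blood
# flows (mL/s) for a 4 kg animal. Tabulated units; the loader converts to L, L/h.
species: monkey
body_weight_kg: 4
units: {volume: mL, flow: mL/s}
gfr_L_per_h: 0.624        # ~10.4 mL/min for a 4 kg macaque
hematocrit: 0.41
compartments:
  lung:          {volume: 34,       flow: 8.6929}
  arterial:      {volume: 107,      flow: 8.6929}
  venous:        {volume: 213,      flow: 8.6929}
  adipose:       {volume: 437,      flow: 0.2670}
  muscle:        {volume: 2000,     flow: 1.5}
  liver:         {volume: 93.46,    flow: 2.4225}
  acat_gut:      {volume: 0,        flow: 1.6667}
  spleen:        {volume: 2.85,     flow: 0.0476}
  heart:         {volume: 13.6,     flow: 0.7572}
  brain:         {volume: 89,       flow: 1.2291}
  kidney:        {volume: 12.4,     flow: 1.1978}
  skin:          {volume: 400,      flow: 0.9}
  reproductive:  {volume: 22,       flow: 0.077}
  red_marrow:    {volume: 36,       flow: 0.18}
  yellow_marrow: {volume: 102,      flow: 0.051}
  rest_of_body:  {volume: 222.6144, flow: 0.1113}
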