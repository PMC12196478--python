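# Mouse whole-body physiology: compartment volumes (mL) and blood flows (mL/s)
# for a 0.025 kg animal. Tabulated units; the loader converts to L and L/h.
species: mouse
body_weight_kg: 0.025
units: {volume: mL, flow: mL/s}
gfr_L_per_h: 0.0168       # standard laboratory-mouse glomerular filtration rate
hematocrit: 0.45
compartments:
  lung:          {volume: 0.1583,  flow: 0.1135}
  arterial:      {volume: 0.57,    flow: 0.1135}
  venous:        {volume: 1.13,    flow: 0.1135}
  adipose:       {volume: 1.9105,  flow: 0.0013}
  muscle:        {volume: 9.2219,  flow: 0.0152}
  liver:         {volume: 1.6636,  flow: 0.0335}
  acat_gut:      {volume: 0,       flow: 0.0250}
  spleen:        {volume: 0.1008,  flow: 0.0015}
  heart:         {volume: 0.1092,  flow: 0.0047}
  brain:         {volume: 0.4165,  flow: 0.0076}
  kidney:        {volume: 0.3893,  flow: 0.0213}
  skin:          {volume: 3.5158,  flow: 0.0101}
  reproductive:  {volume: 0.1480,  flow: 0.0005}
  red_marrow:    {volume: 0.8320,  flow: 0.0136}
  yellow_marrow: {volume: 0.5245,  flow: 0.0009}
  rest_of_body:  {volume: 1.3735,  flow: 0.0050}
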