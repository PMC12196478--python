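# Human whole-body physiology: compartment volumes (mL) and blood flows (mL/s)
# for a 70 kg adult. Tabulated units; the loader converts to L and L/h.
species: human
body_weight_kg: 70
units: {volume: mL, flow: mL/s}
gfr_L_per_h: 7.5          # 125 mL/min, standard adult glomerular filtration rate
hematocrit: 0.45
compartments:
  lung:          {volume: 914.4144,   flow: 85.7230}
  arterial:      {volume: 189.8027,   flow: 85.7230}
  venous:        {volume: 3619.6054,  flow: 85.7230}
  adipose:       {volume: 23762.7391, flow: 8.3374}
  muscle:        {volume: 17027.0270, flow: 8.9701}
  liver:         {volume: 13440.0901, flow: 21.6172}
  acat_gut:      {volume: 0,          flow: 12.0432}
  spleen:        {volume: 142.1316,   flow: 2.4960}
  heart:         {volume: 265.2499,   flow: 3.4004}
  brain:         {volume: 1411.5727,  flow: 12.6419}
  kidney:        {volume: 231.8303,   flow: 14.9815}
  skin:          {volume: 1608.1081,  flow: 3.3887}
  reproductive:  {volume: 26.3200,    flow: 0.0971}
  red_marrow:    {volume: 965.3183,   flow: 5.0855}
  yellow_marrow: {volume: 2683.2505,  flow: 1.4136}
  rest_of_body:  {volume: 10989.8249, flow: 5.7896}
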