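# Rat whole-body physiology: compartment volumes (mL) and blood flows (mL/s),
# GastroPlus-style whole-body compartment set scaled to a 0.25 kg animal.
# Units here are the tabulated ones; the loader converts to L and L/h.
species: rat
body_weight_kg: 0.25
units: {volume: mL, flow: mL/s}
gfr_L_per_h: 0.0786       # standard laboratory-rat glomerular filtration rate
hematocrit: 0.46
compartments:
  lung:          {volume: 2.1,     flow: 0.7990}
  arterial:      {volume: 5.6,     flow: 0.7990}
  venous:        {volume: 11.3,    flow: 0.7990}
  adipose:       {volume: 10,      flow: 0.0067}
  muscle:        {volume: 122,     flow: 0.1251}
  liver:         {volume: 10.3,    flow: 0.1967}
  acat_gut:      {volume: 0,       flow: 0.1250}
  spleen:        {volume: 0.6,     flow: 0.01}
  heart:         {volume: 1.2,     flow: 0.0650}
  brain:         {volume: 1.2371,  flow: 0.0217}
  kidney:        {volume: 3.7,     flow: 0.1533}
  skin:          {volume: 40.0,    flow: 0.0957}
  reproductive:  {volume: 2.5,     flow: 0.0083}
  red_marrow:    {volume: 1.8641,  flow: 0.0304}
  yellow_marrow: {volume: 4.1480,  flow: 0.0068}
  rest_of_body:  {volume: 24.421,  flow: 0.0884}
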