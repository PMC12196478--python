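# Dog whole-body physiology: compartment volumes (mL) and blood flows (mL/s)
# for a 10 kg beagle. Tabulated units; the loader converts to L and L/h.
species: dog
body_weight_kg: 10
units: {volume: mL, flow: mL/s}
gfr_L_per_h: 3.678        # ~61 mL/min for a 10 kg dog
hematocrit: 0.42
compartments:
  lung:          {volume: 86.6667,   flow: 18.4029}
  arterial:      {volume: 300,       flow: 18.4029}
  venous:        {volume: 600,       flow: 18.4029}
  adipose:       {volume: 1637.5546, flow: 0.5830}
  muscle:        {volume: 4385.2065, flow: 4.1659}
  liver:         {volume: 303.2710,  flow: 5.1501}
  acat_gut:      {volume: 0,         flow: 3.5965}
  spleen:        {volume: 24.6679,   flow: 0.4167}
  heart:         {volume: 76.6990,   flow: 0.9}
  brain:         {volume: 76.2910,   flow: 0.8643}
  kidney:        {volume: 50,        flow: 3.6}
  skin:          {volume: 774.2045,  flow: 2.3017}
  reproductive:  {volume: 16.4,      flow: 0.0574}
  red_marrow:    {volume: 135,       flow: 0.3933}
  yellow_marrow: {volume: 64.6,      flow: 0.0188}
  rest_of_body:  {volume: 736.7420,  flow: 0.3684}
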