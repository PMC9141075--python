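from,O1a,O2,O3,exit
O1a,0.700,0.003,0.010,0.287
O2,0.100,0.850,0.020,0.030
O3,0.420,0.010,0.500,0.070
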