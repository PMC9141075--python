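from,N1,N2,N3,O1n,exit
N1,0.97,0.01,0.00,0.00,0.02
N2,0.00,0.90,0.05,0.00,0.05
N3,0.00,0.00,0.75,0.02,0.23
O1n,0.04,0.00,0.04,0.77,0.16
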