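from,N1,N2,N3,O1n,O1a,O2,O3
N1,1,1,1,0,0,0,0
N2,0,1,1,0,0,0,0
N3,0,0,1,1,0,0,0
O1n,0,0,1,1,1,0,0
O1a,0,0,0,1,1,0,0
O2,0,0,0,1,1,1,0
O3,0,0,0,1,1,1,1
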