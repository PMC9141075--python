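from,N1,N2,N3,O1n,O1a,O2,O3
N1,1,1,1,1,1,1,1
N2,1,1,1,1,1,1,1
N3,1,1,1,1,1,1,1
O1n,1,1,1,1,1,1,1
O1a,1,1,1,1,1,1,1
O2,1,1,1,1,1,1,1
O3,1,1,1,1,1,1,1
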