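rate_pct,frequency
0,3
2,8
4,20
5,96
7,71
9,114
11,26
13,12
15,7
16,5
18,3
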