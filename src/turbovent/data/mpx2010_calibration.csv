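pressure_cmH2O,offset_subtracted_analog
0,0
1,5
2,10
3,14
4,19
5,24
6,29
7,33
8,38
9,43
10,48
11,53
12,57
13,62
14,67
15,72
16,77
17,81
18,86
19,91
20,96
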