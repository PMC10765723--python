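subject,LT1,VT1,HRmaxT1,DFAa1T1,DDFAT1,LT2,VT2,HRmaxT2,DFAa1T2,DDFAT2
1,150,171,141,153,138,177,186,171,168,178
2,145,160,137,157,132,171,177,166,175,174
3,135,162,158,162,134,171,171,192,177,168
4,144,157,130,165,146,163,172,157,173,171
5,169,182,144,188,163,186,194,175,194,188
6,123,164,144,158,144,148,179,174,175,182
7,131,149,122,155,126,151,161,148,163,151
8,125,150,131,169,122,153,174,159,179,185
9,150,169,142,181,154,172,187,172,189,188
10,153,158,133,146,127,169,173,162,157,162
11,140,164,132,166,119,163,174,160,176,179
12,141,157,122,161,132,159,165,148,165,159
13,133,151,126,157,129,153,168,153,169,162
14,135,156,131,159,128,161,173,160,165,157
15,160,179,144,173,140,181,196,175,188,181
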