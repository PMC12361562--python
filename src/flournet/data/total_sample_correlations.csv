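,H,LS,MH,PH,SP,W,PG,GU,C,SR,E,WS
H,1.000,0.657,0.513,0.437,0.433,0.580,0.363,0.289,0.456,0.462,0.300,0.278
LS,0.657,1.000,0.466,0.387,0.407,0.603,0.339,0.259,0.443,0.461,0.326,0.301
MH,0.513,0.466,1.000,0.561,0.519,0.515,0.432,0.329,0.482,0.465,0.232,0.210
PH,0.437,0.387,0.561,1.000,0.393,0.426,0.358,0.300,0.359,0.357,0.210,0.185
SP,0.433,0.407,0.519,0.393,1.000,0.523,0.477,0.395,0.517,0.494,0.162,0.140
W,0.580,0.603,0.515,0.426,0.523,1.000,0.430,0.334,0.474,0.467,0.254,0.237
PG,0.363,0.339,0.432,0.358,0.477,0.430,1.000,0.464,0.418,0.390,0.110,0.097
GU,0.289,0.259,0.329,0.300,0.395,0.334,0.464,1.000,0.336,0.309,0.086,0.069
C,0.456,0.443,0.482,0.359,0.517,0.474,0.418,0.336,1.000,0.731,0.196,0.181
SR,0.462,0.461,0.465,0.357,0.494,0.467,0.390,0.309,0.731,1.000,0.206,0.189
E,0.300,0.326,0.232,0.210,0.162,0.254,0.110,0.086,0.196,0.206,1.000,0.734
WS,0.278,0.301,0.210,0.185,0.140,0.237,0.097,0.069,0.181,0.189,0.734,1.000
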