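node_i,node_j,weight,significant
H,LS,0.410,1
H,MH,0.120,1
H,PH,0.085,1
H,SP,0.030,1
H,W,0.170,1
H,PG,0.026,1
H,GU,0.011,0
H,C,0.039,1
H,SR,0.071,1
H,E,0.038,1
H,WS,0.030,1
LS,MH,0.078,1
LS,PH,0.047,1
LS,SP,0.001,0
LS,W,0.260,1
LS,PG,-0.008,0
LS,GU,0.012,1
LS,C,0.028,1
LS,SR,0.075,1
LS,E,0.066,1
LS,WS,0.043,1
MH,PH,0.310,1
MH,SP,0.120,1
MH,W,0.080,1
MH,PG,0.091,1
MH,GU,0.018,0
MH,C,0.071,1
MH,SR,0.039,1
MH,E,0.001,0
MH,WS,0.021,0
PH,SP,0.025,1
PH,W,0.052,1
PH,PG,0.061,1
PH,GU,0.058,1
PH,C,0.000,0
PH,SR,0.014,1
PH,E,0.048,1
PH,WS,0.014,1
SP,W,0.190,1
SP,PG,0.150,1
SP,GU,0.120,1
SP,C,0.130,1
SP,SR,0.075,1
SP,E,0.008,0
SP,WS,0.009,0
W,PG,0.099,1
W,GU,0.029,1
W,C,0.039,1
W,SR,0.033,1
W,E,0.010,0
W,WS,0.013,1
PG,GU,0.270,1
PG,C,0.061,1
PG,SR,0.031,1
PG,E,-0.008,0
PG,WS,-0.004,0
GU,C,0.033,1
GU,SR,0.027,1
GU,E,-0.006,0
GU,WS,0.000,0
C,SR,0.550,1
C,E,0.003,0
C,WS,0.009,0
SR,E,0.015,1
SR,WS,0.016,1
E,WS,0.650,1
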