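item,expected_influence,predictability
LS,1.010,0.523
MH,0.931,0.406
H,1.019,0.515
SR,0.904,0.507
C,0.951,0.512
W,0.948,0.454
PG,0.783,0.300
SP,0.831,0.352
WS,0.746,0.471
E,0.805,0.478
PH,0.689,0.298
GU,0.535,0.197
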