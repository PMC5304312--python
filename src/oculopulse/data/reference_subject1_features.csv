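measurement,w1_ms,w2_ms,w3_mm,w4_hz,w5_mmHg
1,7.363,21.444,1.015,432,15
2,7.331,21.646,1.039,421,14.5
3,7.64,21.468,1.091,407,15
4,7.693,21.672,1.069,409,16
5,7.365,21.574,1.02,420,15
6,7.46,21.394,1.024,432,16
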