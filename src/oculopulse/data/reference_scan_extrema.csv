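subject,r_min,phi_min_deg,r_max,phi_max_deg
1,-0.95,230,0.95,50
2,-0.91,250,0.91,70
3,-0.95,220,0.95,40
4,-0.48,340,0.48,160
5,-0.88,130,0.88,310
6,-0.16,50,0.16,230
7,-0.51,100,0.5,160
8,-0.99,150,0.99,330
9,-0.66,200,0.66,20
10,-0.69,230,0.69,50
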