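subject,eye,w1_mean,w1_std,w2_mean,w2_std,w3_mean,w3_std,w4_mean,w4_std,w5_mean,w5_std
1,right,7.41,0.15,21.54,0.11,1.03,0.03,416,1.7,15.25,0.6
2,right,7.38,0.22,21.86,0.51,1.04,0.03,430,3.1,14.9,2.31
3,right,7.25,0.32,22.05,0.09,1.08,0.033,444,3.7,12.41,0.49
4,right,7.30,0.11,21.78,0.18,1.08,0.04,401,2.0,14.33,1.08
5,right,6.61,0.08,22.81,0.15,1.17,0.03,399,4.7,7.9,0.63
6,left,6.71,0.06,22.63,0.09,1.11,0.02,409,3.1,8.08,0.73
7,left,6.91,0.03,22.13,0.05,1.15,0.01,434,5.1,10.08,0.28
8,left,6.91,0.06,22.13,0.15,1.16,0.02,421,1.4,10.08,0.76
9,left,7.29,0.13,21.94,0.3,1.03,0.045,409,2.2,13.9,1.5
10,left,7.09,0.11,22.43,0.2,1.15,0.06,389,3.7,12.1,1.08
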