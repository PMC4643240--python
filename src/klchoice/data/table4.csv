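subject,precision,snack1,snack2,snack3,snack4,snack5,snack6,correlation
1,3.22,0,-3.11,1.18,-5.18,1.03,-2.53,0.78
2,2.71,0,-10.00,8.70,3.38,2.72,-9.99,0.70
3,4.42,0,5.23,2.85,-10.00,2.56,6.88,0.93
4,2.27,0,6.59,3.41,3.35,-10.00,6.26,0.95
5,2.39,0,-0.89,-4.63,0.05,-10.00,-1.66,0.96
6,2.00,0,0.13,4.12,-10.00,1.73,5.53,0.93
7,6.16,0,1.67,-4.84,-0.02,-6.22,1.12,0.38
8,5.39,0,-2.49,0.65,-0.73,-5.58,-3.59,0.93
9,2.10,0,-2.72,-10.00,-1.55,-0.97,-2.18,0.97
10,2.00,0,-0.86,-10.00,-1.16,-2.98,-2.19,0.94
11,8.00,0,-3.92,-2.71,5.26,0.89,-4.19,0.59
12,4.51,0,-3.04,-0.35,-2.77,-8.80,-2.44,0.86
13,8.00,0,-3.89,-3.57,-4.82,-2.35,-1.98,0.93
14,6.61,0,-0.02,0.02,0.01,0.42,0.03,0.95
15,2.70,0,1.19,2.95,3.00,-6.82,0.05,0.71
16,6.73,0,-7.37,-10.00,-0.54,3.56,-3.58,0.82
17,8.00,0,-3.82,-5.89,-1.61,-7.37,-5.64,0.96
18,4.39,0,-5.75,2.31,4.39,4.94,3.14,0.71
19,8.00,0,9.17,-10.00,2.07,2.62,3.77,0.98
20,2.00,0,0.67,-3.05,0.45,-0.39,0.24,0.97
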