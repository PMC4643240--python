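subject,expected_utility,expected_utility_stars,risk,risk_stars,entropy_gain,entropy_gain_stars
1,6.33,2,-2.83,1,-0.02,0
2,8.36,2,10.47,2,-1.18,2
3,8.14,2,-7.49,0,-0.82,2
4,16.96,2,-10.28,2,0.86,2
5,14.94,2,5.63,0,1.87,2
6,9.31,2,-13.47,2,0.46,1
7,0.47,0,8.59,2,-1.27,2
8,24.04,2,19.66,2,1.71,2
9,27.63,2,-15.88,0,1.05,2
10,43.80,2,15.02,0,2.78,2
11,6.89,2,4.16,0,4.46,2
12,15.97,2,-39.49,2,1.12,2
13,17.75,2,10.84,2,0.01,0
14,19.06,2,6.22,1,1.69,2
15,18.78,2,-36.16,2,0.28,0
16,10.82,2,-7.33,2,0.83,2
17,9.11,2,-45.29,1,0.97,2
18,30.61,2,6.47,0,0.57,2
19,33.43,2,-20.44,1,1.39,2
20,18.76,2,15.06,2,1.88,2
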