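subject,kl_estimated,eu_estimated,kl_fixed,eu_fixed
1,-239.29,-229.49,-255.92,-226.17
2,-293.71,-222.86,-309.05,-218.61
3,-348.59,-308.61,-445.15,-306.91
4,-170.69,-199.34,-172.67,-206.51
5,-203.75,-242.30,-202.28,-250.35
6,-325.17,-325.38,-339.77,-322.21
7,-369.97,-275.09,-511.98,-270.76
8,-157.99,-180.25,-189.65,-216.45
9,-207.68,-219.64,-202.67,-225.79
10,-180.67,-257.31,-217.53,-274.46
11,-239.47,-420.98,-250.11,-415.55
12,-271.68,-272.59,-273.76,-272.76
13,-184.31,-163.09,-188.14,-187.69
14,-159.99,-197.43,-189.95,-227.23
15,-208.62,-228.41,-203.39,-235.74
16,-178.65,-194.74,-197.41,-217.26
17,-376.28,-384.78,-399.06,-380.96
18,-173.00,-194.42,-196.05,-221.05
19,-228.63,-257.17,-224.27,-260.03
20,-161.95,-182.65,-202.54,-230.35
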