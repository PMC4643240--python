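subject,without_entropy,with_entropy
1,-263.65,-269.33
2,-349.92,-326.58
3,-310.91,-303.47
4,-196.36,-192.60
5,-257.96,-219.29
6,-320.01,-320.78
7,-425.83,-391.45
8,-222.29,-201.65
9,-199.72,-193.29
10,-264.21,-206.91
11,-358.05,-185.59
12,-282.37,-268.50
13,-197.28,-202.96
14,-183.95,-167.31
15,-276.33,-280.31
16,-263.10,-258.83
17,-373.01,-354.93
18,-321.27,-321.06
19,-239.36,-218.97
20,-158.55,-144.98
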