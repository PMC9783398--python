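raw_score,logit,se
0,-4.323,1.2796
1,-3.428,0.9093
2,-2.805,0.7278
3,-2.373,0.6331
4,-2.029,0.5773
5,-1.732,0.5413
6,-1.462,0.5192
7,-1.210,0.5037
8,-0.971,0.4907
9,-0.740,0.4851
10,-0.514,0.4799
11,-0.289,0.4799
12,-0.060,0.4864
13,0.175,0.4907
14,0.420,0.4987
15,0.676,0.5080
16,0.941,0.5192
17,1.213,0.5316
18,1.492,0.5413
19,1.785,0.5638
20,2.103,0.5959
21,2.466,0.6467
22,2.902,0.7278
23,3.485,0.8910
24,4.265,1.2195
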