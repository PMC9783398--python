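raw_score,user24_loc,user24_se,user10_loc,user10_se,user100_loc,user100_se,lmd_loc,lmd_se,sem_loc,sem_se,lsd_loc,lsd_se
0,0,3.6,0,1.5,0,14.9,0,5.1,0,2.5,0,1.8
1,3,2.5,1,1.1,10,10.6,4,3.6,2,1.8,1,1.3
2,4,2.0,2,0.8,18,8.5,6,2.9,3,1.4,2,1.0
3,5,1.8,2,0.7,23,7.4,8,2.5,4,1.2,3,0.9
4,6,1.6,3,0.7,27,6.7,9,2.3,4,1.1,3,0.8
5,7,1.5,3,0.6,30,6.3,10,2.2,5,1.1,4,0.8
6,8,1.5,3,0.6,33,6.0,11,2.1,6,1.0,4,0.7
7,9,1.4,4,0.6,36,5.9,12,2.0,6,1.0,4,0.7
8,9,1.4,4,0.6,39,5.7,13,2.0,7,1.0,5,0.7
9,10,1.4,4,0.6,42,5.6,14,1.9,7,1.0,5,0.7
10,11,1.3,4,0.6,44,5.6,15,1.9,7,0.9,5,0.7
11,11,1.3,5,0.6,47,5.6,16,1.9,8,0.9,6,0.7
12,12,1.4,5,0.6,50,5.7,17,1.9,8,1.0,6,0.7
13,13,1.4,5,0.6,52,5.7,18,2.0,9,1.0,6,0.7
14,13,1.4,6,0.6,55,5.8,19,2.0,9,1.0,7,0.7
15,14,1.4,6,0.6,58,5.9,20,2.0,10,1.0,7,0.7
16,15,1.5,6,0.6,61,6.0,21,2.1,10,1.0,7,0.7
17,15,1.5,6,0.6,64,6.2,22,2.1,11,1.0,8,0.7
18,16,1.5,7,0.6,68,6.3,23,2.2,11,1.1,8,0.8
19,17,1.6,7,0.7,71,6.6,24,2.3,12,1.1,9,0.8
20,18,1.7,7,0.7,75,6.9,26,2.4,13,1.2,9,0.8
21,19,1.8,8,0.8,79,7.5,27,2.6,13,1.3,10,0.9
22,20,2.0,8,0.8,84,8.5,29,2.9,14,1.4,10,1.0
23,22,2.5,9,1.0,91,10.4,31,3.6,15,1.7,11,1.2
24,24,3.4,10,1.4,100,14.2,34,4.9,17,2.4,12,1.7
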