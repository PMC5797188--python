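scan,auto_mean,auto_sd,auto_median,auto_max,semi_mean,semi_sd,semi_median,semi_max,corrected
1,7.9,7.5,5.4,29,7.9,7.5,5.4,29,0
2,4.5,4.0,3.2,15,4.5,4.0,3.2,15,0
3,6.9,5.8,4.6,19,6.9,5.8,4.6,19,0
4,6.6,6.1,4.0,21,6.6,6.1,4.0,21,0
5,7.9,6.3,5.6,31,7.9,6.3,5.6,31,0
6,7.9,8.2,3.7,32,7.9,8.2,3.7,32,0
7,4.8,3.9,3.7,15,4.8,3.9,3.7,15,0
8,4.2,3.7,2.5,15,4.2,3.7,2.5,15,0
9,5.9,5.9,3.5,23,5.9,5.9,3.5,23,0
10,5.2,4.8,3.4,21,5.2,4.8,3.4,21,0
11,4.4,3.5,3.5,18,4.4,3.5,3.5,18,0
12,13.3,18.2,5.2,69,7.0,5.0,3.3,15,1
13,5.4,2.8,4.1,14,5.4,2.8,4.1,14,0
14,4.7,5.2,2.4,24,4.7,5.2,2.4,24,0
15,14.0,19.2,3.9,55,3.9,2.1,3.4,9,1
16,4.1,3.5,3.0,16,4.1,3.5,3.0,16,0
17,4.2,3.0,3.3,12,4.2,3.0,3.3,12,0
18,3.9,2.8,3.2,12,3.9,2.8,3.2,12,0
19,11.4,14.8,4.5,49,4.2,2.9,3.9,15,1
20,4.6,3.1,3.5,14,4.6,3.1,3.5,14,0
21,5.5,6.4,3.3,27,5.5,6.4,3.3,27,0
22,6.5,5.4,4.8,21,6.5,5.4,4.8,21,0
23,3.8,2.9,2.7,13,3.8,2.9,2.7,13,0
24,6.7,7.1,4.4,27,6.7,7.1,4.4,27,0
25,4.5,2.8,3.7,13,4.5,2.8,3.7,13,0
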