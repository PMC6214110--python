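compound_id,exp_ic50_uM,est_ic50_uM,printed_error,printed_exp_scale,printed_est_scale
1,0.107,0.128,+1.2,++++,++++
2,0.194,0.119,-1.6,++++,++++
3,0.481,0.511,+1.1,++++,++++
4,1.8,2.8,+1.6,+++,+++
5,2.8,5.9,+2.1,+++,+++
6,2.8,2.8,-1,+++,+++
7,3.2,5.9,+1.8,+++,+++
8,3.5,3.9,+1.1,+++,+++
9,4.4,6.7,+1.5,+++,+++
10,5.7,5.5,-1,+++,+++
11,6.2,5,-1.2,+++,+++
12,7.9,6.1,-1.3,+++,+++
13,9,9.6,+1.1,++,++
14,13.3,9.2,-1.4,++,++
15,16.3,9.4,-1.7,++,++
16,18,21.3,+1.2,+,+
17,23,9.2,-2.5,+,++
18,25.9,26.7,+1,+,+
19,27,31.8,+1.2,+,+
20,29.2,26.6,-1.1,+,+
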