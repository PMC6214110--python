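compound_id,exp_ic50_uM,est_ic50_uM,printed_error,printed_exp_scale,printed_est_scale
1,0.301,0.111,-2.7,++++,++++
2,0.512,0.195,-2.6,++++,++++
3,1.02,0.399,-2.6,+++,++++
4,2.9,3.3,+1.1,+++,+++
5,3.9,3.6,-1.1,+++,+++
6,4.4,5.7,+1.3,+++,+++
7,4.9,6.7,+1.4,+++,+++
8,5.2,3.2,-1.6,+++,+++
9,5.2,6.4,+1.2,+++,+++
10,5.4,4.4,-1.2,+++,+++
11,5.6,6.7,+1.2,+++,+++
12,5.7,4.4,-1.3,+++,+++
13,6,4.9,-1.2,+++,+++
14,6.3,5.6,-1.1,+++,+++
15,6.3,9.2,+1.5,+++,++
16,6.5,3.3,-2,+++,+++
17,7.7,6.6,-1.2,+++,+++
18,7.9,7.9,-1,+++,+++
19,8.4,10.6,+1.3,++,++
20,10.8,9.5,-1.1,++,++
21,11.2,13.3,+1.2,++,++
22,12,6.1,-2,++,+++
23,12.3,6.6,-1.9,++,+++
24,13.1,9.1,-1.4,++,++
25,15,11,-1.4,++,++
26,15.6,9.3,-1.7,++,++
27,16,14.5,-1.1,++,++
28,17.3,9.7,-1.8,++,++
29,21.2,28.4,+1.3,+,+
30,22,11.4,-1.9,+,++
31,23.5,31.4,+1.3,+,+
32,28.7,31.3,+1.1,+,+
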