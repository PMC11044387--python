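individual,sex,age,ndi_points,ndi_pct,ks_c4c5,ks_c5c6,ks_c6c7,sequence_t1,sequence_t2
1,M,58,0,0,1,1,1,-,-
2,F,55,3,6,1,1,1,-,-
3,F,67,2,4,1,2,2,-,-
4,M,67,3,6,3,3,3,-,-
5,F,64,0,0,1,1,2,-,-
6,M,63,0,0,3,3,2,-,-
7,M,60,2,4,2,1,1,-,-
8,M,57,0,0,1,1,1,-,-
9,F,59,0,0,1,1,3,-,-
10,M,61,0,0,1,1,2,+,-
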