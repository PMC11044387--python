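individual,timepoint,trom,srom_c4c5,srom_c5c6,srom_c6c7,sequence
E1,T1,11.2,7.4,1.0,2.8,-
E1,T2,12.4,6.2,3.3,2.8,-
E2,T1,10.6,4.2,4.4,2.0,-
E2,T2,10.3,4.1,5.4,0.7,-
E3,T1,8.2,2.2,2.5,3.5,-
E3,T2,12.6,4.0,4.2,4.3,-
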