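individual,timepoint,trom,srom_c4c5,srom_c5c6,srom_c6c7
1,T1,23.2,14.7,0.2,8.3
2,T1,55.8,23.9,20.9,11.0
3,T1,13.1,6.5,2.7,4.0
4,T1,25.2,4.9,0.2,20.2
5,T1,21.1,13.1,4.7,3.3
6,T1,24.9,9.7,8.2,7.0
7,T1,15.5,10.2,4.7,0.6
8,T1,16.4,9.2,7.3,0.2
9,T1,27.4,9.1,14.7,3.7
10,T1,35.5,10.2,15.3,10.1
1,T2,15.3,3.6,5.0,6.8
2,T2,53.5,14.5,17.5,21.6
3,T2,10.8,4.4,2.9,3.5
4,T2,8.1,5.9,1.0,1.1
5,T2,19.4,12.5,3.5,3.4
6,T2,22.1,11.1,6.4,4.5
7,T2,23.9,14.5,5.7,3.8
8,T2,13.9,6.5,4.8,2.6
9,T2,22.4,11.5,8.6,2.3
10,T2,33.6,8.9,15.2,9.5
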