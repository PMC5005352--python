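sample_id,depth_mbsf,Asp,Glu,Ser,His,Gly,Thr,Arg,beta-Ala,Tau,Ala,gamma-Aba,Tyr,Val,Phe,Ile,Leu,Orn,Lys
LD00,0.4,5.8,8.5,8.1,0.9,11.7,9.1,5.1,0,0,14.2,0,3.1,8.4,5.0,4.4,10.3,0,5.2
LD01,2.75,5.0,8.4,13.0,0.7,31.5,5.2,3.7,0,0,8.4,0,2.8,4.4,3.4,2.2,6.7,0,4.7
LD02,4.32,4.5,8.8,10.5,0.9,14.0,6.8,5.8,0,0,10.6,0,3.6,6.9,3.6,10.0,8.8,0,5.2
LD03,9.57,9.4,12.3,11.8,1.0,18.3,4.7,4.7,0,0,7.6,0,3.2,5.0,3.5,3.0,10.2,0,5.4
LD04,14.55,5.8,7.5,7.7,0.6,13.2,8.5,4.4,0,0,16.0,0,2.8,8.5,5.0,4.0,10.3,0,5.9
LD05,20.53,10.9,10.7,5.1,0.9,7.5,7.2,4.6,0,0,16.0,0,2.9,8.8,4.9,3.8,12.0,0,4.7
LD06,38.95,10.0,14.1,11.7,1.2,14.4,4.7,5.2,0,0,6.7,0,3.4,5.5,3.8,1.3,12.5,0,5.5
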