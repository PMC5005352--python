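sample_id,depth_mbsf,thaa_fmol_per_cell,thaa_c_fmol_per_cell
LD00,0.4,0.18,0.88
LD01,2.75,0.29,1.2
LD02,4.32,0.28,1.3
LD03,9.57,0.31,1.4
LD04,14.55,0.21,0.97
LD05,20.53,0.13,0.66
LD06,38.95,0.17,0.78
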