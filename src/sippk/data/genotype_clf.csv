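genotype,cl_f_l_per_h
*1/*1,4.01
*1/*2,2.78
*2/*2,1.49
*2/*3,1.35
*3/*3,0.90
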