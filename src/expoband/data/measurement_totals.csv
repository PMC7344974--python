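task,n,am_ppm,gm_ppm,gsd,min_ppm,max_ppm
FRP lamination,137,21.80,13.07,2.86,1.07,186.34
Inspection,23,0.45,0.23,4.25,0.01,1.43
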