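peak,compound,DPPH_vip,DPPH_coef,FRAP_vip,FRAP_coef
1,Caftaric acid,1.52,0.40,1.45,0.35
3,5-O-caffeoylquinic acid,1.15,0.29,1.05,0.26
5,Caffeic acid,1.03,0.28,1.28,0.43
7,Cichoric acid,1.39,0.19,1.28,0.12
18,Luteolin,0.89,0.24,1.01,0.31
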