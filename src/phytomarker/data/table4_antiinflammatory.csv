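peak,compound,NO_inhibition_vip,NO_inhibition_coef
8,p-Coumaric acid,1.32,0.13
9,Luteolin-7-O-beta-D-gentiobioside,1.28,0.12
13,Luteolin-7-O-beta-D-glucoside,1.31,0.13
17,Isorhamnetin-3-O-beta-D-glucoside,1.01,0.11
18,Luteolin,1.07,0.13
19,Kaempferol,1.82,0.21
20,Apigenin,1.31,0.16
21,Eupalitin,1.53,0.17
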