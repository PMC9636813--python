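peak,DPPH,FRAP,anti_inflammatory
1,0.971,0.974,0.966
2,0.911,0.910,0.908
3,0.964,0.967,0.961
4,0.914,0.910,0.908
5,0.967,0.974,0.972
6,0.936,0.926,0.917
7,0.963,0.957,0.951
8,0.939,0.939,0.939
9,0.957,0.959,0.960
10,0.951,0.949,0.948
11,0.963,0.961,0.955
12,0.961,0.966,0.968
13,0.948,0.944,0.931
14,0.959,0.962,0.956
15,0.919,0.925,0.932
16,0.911,0.910,0.913
17,0.948,0.955,0.961
18,0.935,0.945,0.953
19,0.924,0.934,0.948
20,0.904,0.906,0.914
21,0.914,0.914,0.917
22,0.940,0.950,0.971
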