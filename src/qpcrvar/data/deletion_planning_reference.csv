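k,level_pct,sd,n_1pct,n_2pct,n_5pct,n_10pct,n_20pct
3,10,1.83,54,15,4,3,2
3,20,1.64,44,12,4,2,2
3,30,1.45,35,10,3,2,2
3,40,1.27,27,8,3,2,2
3,50,1.09,20,6,3,2,2
3,60,0.92,15,5,3,2,2
3,70,0.76,11,4,2,2,2
3,80,0.62,8,3,2,2,2
3,90,0.52,6,3,2,2,2
6,10,1.34,30,9,3,2,2
6,20,1.21,24,7,3,2,2
6,30,1.08,20,6,3,2,2
6,40,0.96,16,5,3,2,2
6,50,0.84,13,5,2,2,2
6,60,0.73,10,4,2,2,2
6,70,0.64,8,3,2,2,2
6,80,0.56,6,3,2,2,2
6,90,0.50,6,3,2,2,2
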