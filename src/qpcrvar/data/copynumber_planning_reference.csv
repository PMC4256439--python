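k,concentration,n_10pct,n_20pct,n_30pct,n_40pct,n_50pct
3,high,6,3,3,2,2
3,moderate,8,4,3,3,2
3,low,25,8,5,4,3
6,high,5,3,2,2,2
6,moderate,6,3,3,2,2
6,low,16,6,4,3,3
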