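order,Tl,Km,gamma_star,Vcmax25,Jmax25,Rd25
1,31.06,"1,173.59",54.60,39.09,68.87,1.45
2,33.13,"1,406.20",60.43,56.58,86.11,2.58
3,29.18,"1,000.11",50.21,24.53,54.20,1.72
4,36.69,"1,911.34",71.66,43.98,65.02,2.30
5,27.81,885.32,46.47,51.85,103.61,0.81
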