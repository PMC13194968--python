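metal,ASV,UCC
As,13,4.8
Pb,20,17
Zn,95,67
Fe,47200,39200
Cd,0.3,0.09
Cu,45,28
Cr,90,92
Ni,68,47
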