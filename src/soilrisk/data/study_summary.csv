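metal,min,max,mean,sd,cv_percent,skewness,kurtosis
As,5.10,161.56,15.97,34.40,215,4.4,19
Pb,49.00,364.00,147.12,110.76,75,0.9,-1
Zn,159.00,1851.00,480.73,406.08,84,2.5,6
Fe,15750,63840,28136,11233.63,40,1.9,5
Cd,1.00,12.00,5.27,2.64,50,0.9,1
Cu,8.00,478.00,55.50,104.16,188,3.9,15
Cr,160.70,538.13,184.85,83.21,45,4.5,19
Ni,65.00,101.00,73.50,7.29,10,3.0,11
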