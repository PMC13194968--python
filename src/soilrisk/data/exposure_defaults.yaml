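# Default receptor exposure profiles (USEPA RAGS / RSL conventions).
# Units: ing_r mg/day; inh_r m3/day; ef_d days/year; ed years; bw kg;
# at_nc, at_ca days; sa cm2; af mg/cm2/day; pef m3/kg.
# at_nc follows the ED x 365 convention; at_ca uses a 70-year lifetime.
child:
  ing_r: 200.0
  inh_r: 7.6
  ef_d: 350.0
  ed: 6.0
  bw: 15.0
  at_nc: 2190.0
  at_ca: 25550.0
  sa: 2800.0
  af: 0.2
  pef: 1.36e+9
adult:
  ing_r: 100.0
  inh_r: 20.0
  ef_d: 350.0
  ed: 24.0
  bw: 70.0
  at_nc: 8760.0
  at_ca: 25550.0
  sa: 5700.0
  af: 0.07
  pef: 1.36e+9
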