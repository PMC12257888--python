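k1b: 0.00017
k2: 570000.0
k_minus2: 0.07
k3: 1.2e-05
k4: 2.2e-05
kT: 0.093
e430g_factor: 1.2
alpha_prefactors:
  0.05: 1.0
kon_fab_by_surface:
  0.05: 6000.0
koff_fab_by_surface:
  0.05: 0.21
spa:
  kC: 190000.0
  k_minusC: 0.0032
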