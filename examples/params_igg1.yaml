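k1b: 0.00032
k2: 570000.0
k_minus2: 1.5
k3: 0.00025
k4: 0.00065
kT: 0.35
e430g_factor: 1.9
alpha_prefactors:
  0.0085: 2.0
  0.025: 1.5
  0.05: 1.0
kon_fab_by_surface:
  0.0085: 31000.0
  0.025: 28000.0
  0.05: 6000.0
koff_fab_by_surface:
  0.0085: 0.13
  0.025: 0.21
  0.05: 0.21
spa:
  kC: 190000.0
  k_minusC: 0.0032
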