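# Synthetic example C1-binding configuration for the lysis simulator.
# One 1:1 binding site per C1-activating oligomer (tetramer or larger);
# rates are placeholders of plausible magnitude (avidity growing with
# oligomer size) and should be replaced with measured values.
kon_c1:
  4: 2.0e6   # M^-1 s^-1
  5: 2.0e6
  6: 2.0e6
koff_c1:
  4: 2.0e-2  # s^-1
  5: 5.0e-3
  6: 1.0e-3
c1_conc: 1.0e-9  # M
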