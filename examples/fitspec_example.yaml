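# Fit specification for the oligomerization global fit.
# Free parameters use the package's dotted addressing; initial values are
# 3x-perturbed away from the calibrated set.  The 'poisson' objective
# compares absolute particle counts (requires an area_um2 column in the
# count table, as written by `oligokin synth --noise poisson`).
free:
  k1b: 9.6e-4
  k3: 8.3e-5
  k4: 1.95e-3
bounds:
  k1b: [1.0e-6, 1.0e-1]
  k3: [1.0e-7, 1.0e-1]
  k4: [1.0e-7, 1.0e-1]
kind: poisson
n_starts: 1
seed: 1
profile: [k1b]
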