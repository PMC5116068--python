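# Full-scale study conditions: 840 duplexes at the layered state point,
# with a production run of 5e6 sweeps. This reproduces the reference
# conditions but takes days of CPU time; the test-suite and acceptance
# script use the scaled-down N=128 runs instead.
model:
  L: 16.0
  D: 3.0
  sigma: 6.3
  delta: 0.75
  beta_u0: 8.06
mc:
  beta_P_v0: 4.1
  n_equil: 1000000
  n_prod: 5000000
  sample_every: 1000
  seed: 1
  cluster_volume_moves: true
system:
  n: 840
  start: crystal
  target_packing: 0.55
output:
  trajectory: full_run.xyz
  observables: full_obs.csv
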