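# Shared configuration for the numbered analysis scripts.
# A desk-scale landscape: 60 x 60 grid of 800 m cells, 40 populations of
# 10 seedlings, 60 adaptive SNPs (logistic clines, |b| in [1.5, 3]) and
# 300 neutral SNPs (Balding-Nichols F = 0.1).
out_dir: results/run
seed: 11
n_trees: 200
subsample: 2000
backward_k: [4, 9]
simulation:
  grid_shape: [60, 60]
  n_populations: 40
  samples_per_population: 10
  n_adaptive: 60
  n_neutral: 300
  correlation_length: 10
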