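# Demo: toy metabolic model + synthetic paired cohort with planted effects.
model: toy
outdir: results/demo
seed: 1
thresholds:
  fdr_alpha: 0.05
  lfc_min: 0.01
flux:
  percentile: 95.0
consensus:
  k_min: 2
  k_max: 10
  reps: 30
  subsample: 0.8
  threshold: 0.5
synthetic:
  n_pairs: 7
  n_genes: 200
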