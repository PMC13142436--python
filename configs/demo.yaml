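# Demo pipeline: synthetic inputs with planted ground truth, all stages.
seed: 17
outdir: results/demo

synthetic:
  n_samples_per_group: 4
  n_peptides: 1500
  planted_ip_fraction: {untreated: 0.70, IFNg: 0.85}
  planted_len_fraction: {untreated: 0.55, IFNg: 0.70}
  n_features: 800
  n_de: 80
  de_log2fc: 2.0
  missing_rate: 0.05
  n_proteins: 60
  acidic_enrichment_delta: 0.08

peptidome:
  n_tau_peptides: 300
  tau_ip_fraction: 0.90

differential:
  knn_k: 5
  fdr: 0.05

classifier:
  n_splits: 20
  train_frac: 0.7
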