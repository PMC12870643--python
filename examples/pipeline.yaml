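# Complete pipeline configuration: simulate -> qc -> deconvolve ->
# technical PCs -> EWAS (+ sensitivity, never-smokers) -> annotation ->
# MRS sweep -> external replication. Every stage's randomness derives
# from the single seed below.
seed: 42

simulate:
  n_samples: 500
  n_probes: 3000
  n_cases: 150
  n_causal: 8
  causal_effect_range: [0.02, 0.04]
  n_smoking_probes: 10
  confounding_strength: 0.2

qc:
  fail_alpha: 0.05
  max_fail_fraction: 0.10
  pass_alpha: 0.05
  min_pass_fraction: 0.96
  # blocklist: path/to/blocklist.txt   # one probe id per line

ewas:
  n_technical_pcs: 5
  n_ancestry_pcs: 10
  use_computed_ews_threshold: true   # 0.05 / n_probes; false -> ews_alpha
  ews_alpha: 5.88e-08
  min_cases_sensitivity: 50

mrs:
  discovery_fraction: 0.75
  r_cutoff: 0.3
  stratify: false
  n_bootstrap: 1000

replication:
  n_samples: 1000
  n_cases: 300
  attenuation: 1.0     # 0.0 emulates a cohort where the signal is absent

enrichment:
  gene_sets: null      # path to a GMT file enables the stage
  relaxed_threshold: 5.0e-05
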