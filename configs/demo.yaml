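# Demo pipeline configuration: synthetic cohort, all stages enabled.
simulation:
  n_samples: 300
  n_blocks: 10
  snps_per_block: 5
  within_block_r2: 0.8
  maf_range: [0.1, 0.4]
  eqtl_beta: 1.0
  fusion_fraction: 0.4
  fusion_dependent: true
  coexpr_rho: 0.8
  noise_sd: 1.0
  cooccupancy_target: 0.7
  snp_enrichment_fold: 3.0
  surv_lnHR: 0.7
  censor_rate: 0.2
  seed: 0

stages:
  simulate: true
  qc: true
  eqtl: true
  coexpression: true
  peaks: true
  snp_enrichment: true
  signatures: true
  survival: true

r2_min: 0.8
coexpr_panel_k: 25
n_permutations: 0
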