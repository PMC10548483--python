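# Full pipeline on a freshly simulated default cohort.
workdir: run
simulate: true
seed: 1
n_patients: 31
min_tpm: 0.0
coding_mb: 31.0
min_group: 10
candidate_source: simulated
survival_covariates: [t_cell_fraction, neoantigen_quality, tmb, nal]
bivariate_pairs:
  - [t_cell_fraction, neoantigen_quality]
  - [t_cell_fraction, tmb]
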