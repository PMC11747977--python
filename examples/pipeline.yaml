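# Demo pipeline: synthetic cohort through classification, agreement and
# the onset prevalence model.  `dyn run --config examples/pipeline.yaml`
out_dir: seizdyn_demo_run
master_seed: 7
simulate:
  n_patients: 10
  seizures_per_patient: 3
  snr_db: 10.0
  n_ic: 6
  n_clear_ic: 2
agreement:
  n_perm: 2000
model:
  side: onset
  chains: 2
  iterations: 1500
  warmup: 500
  covariates: [vigilance]
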