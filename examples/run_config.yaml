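# Full study-replica configuration.
# `pbifpet run-full --config examples/run_config.yaml --out demo_run`
cohort:
  seed: 20210429
  n_subjects: 18
  fraction_pd: 0.6667      # 12 PD / 6 HV
  fraction_hab: 0.5
  n_test_retest: 5
  noise_scale: 0.10
schemes: [weight-dose, auc, weight-auc]
tail_window: [60.0, 90.0]
logan_max_rel_error: 0.10
vb: 0.05
loa_factor: 1.96
write_curves: false
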