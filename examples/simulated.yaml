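# Full benchmark on simulated study conditions.
# All `simulate` keys are SimConfig fields; omitted keys use the defaults
# documented in docs/methods.md.
simulate:
  n_genes: 200
  n_psms_per_sample: 5000
  n_samples: 4
  mouse_psm_fraction: 0.30
  tool_overlap: 0.67
  detection_rate: 0.5
  misloc_rate: 0.2
  wrong_shift_rate: 0.05
  background_rate: 0.05
tolerance: 0.1
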