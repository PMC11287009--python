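# Full simulated analysis from the calibrated generator fixture:
# both cut-off schemes, national initial cohorts, 2019 CN¥ economics.
mode: simulate
generator:
  fixture: ckb-like
  n_subjects: 30000
  seed: 2024
schemes: [three_category, four_category]
n_draws: 500
seed: 2024
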