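# Small demonstration cohort for the end-to-end `mobgait all` run:
# 2 subjects per group, 4 recording days each, daily walking volume scaled
# to 12% of the preset medians, and week-scale signals rendered at 25.6 Hz.
seed: 7
sim:
  fs: 102.4
  pam_fs: 25.6
  n_days: 4
  n_subjects_per_group: 2
  volume_scale: 0.12
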