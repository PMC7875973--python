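# Full-battery benchmark on the default synthetic cohort.
# Run with:  restpred benchmark --config examples/bench.yaml --out artifacts/
# (the full 13-model battery at 120 subjects takes ~30-45 min on one CPU;
#  the masked-PCR features dominate the cost)
sim:
  n_subjects: 120
  task_series_frames: 100   # needed by the task-derived group-ICA model
models:
  - group-mean
  - group-zstat
  - mmp-rr
  - mmp-parcelrr
  - mmp-ols
  - mmp-rr-dr
  - mmp-rr-pcr
  - grp-rr
  - gica-rest-rr
  - gica-task-rr
  - af
  - af-mod
  - anat-rr
split:
  n_train: 60
  n_test: 60
evaluation:
  n_perm: 5000
curves:
  enabled: true
  model: mmp-rr
  train_sizes: [3, 10, 30, 50]
seed: 1
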