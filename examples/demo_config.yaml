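# Demo pipeline configuration: 2 x 8 animals, image-based measurement route.
# Run with:  patreat run --config examples/demo_config.yaml --out demo_run
out_dir: demo_run
seed: 1
use_imaging: true
scene_voxel_spacing: [0.3, 0.2, 0.2]
clamp: flag
auc_preset: standard
cv_k: 5
cv_train_frac: 0.8
cv_repeats: 100
responder_percentile: 25.0
cohort:
  n_control: 8
  n_treated: 8
  treatment_start_day: 11
  treatment_effect: [0.25, 0.125]
  sto2_dip: 15.0
  weekend_recovery: true
  size_limit: 20.0
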