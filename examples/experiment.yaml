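# Full experiment: simulate the 19-participant cohort, evaluate the
# lower-body trio with RF + XGBoost on both tasks, export importance
# grids, then grid-search window settings and device subsets.
simulation:
  n_participants: 19
  seed: 0
window:
  width_s: 5.0
  overlap: 0.0
models:
  - family: random_forest
    seed: 0
  - family: xgboost
    seed: 0
evaluation:
  k: 6
  seed: 0
  tasks: [exercise, posture]
  sensor:
    locations: [lower_back, left_thigh, right_ankle]
    channels: [accelerometer, gyroscope, magnetometer]
  importance: true
search:
  widths_s: [1.0, 2.0, 5.0]
  overlaps: [0.0]
  tasks: [exercise]
  location_sets:
    - [lower_back]
    - [lower_back, left_thigh]
    - [lower_back, left_thigh, right_ankle]
  channel_sets:
    - [accelerometer, gyroscope, magnetometer]
  max_locations: 3
output_dir: imurehab_run
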