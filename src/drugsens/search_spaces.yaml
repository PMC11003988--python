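# Versioned per-family random-search spaces (desk-scale defaults).
# Each parameter is either a list (uniform choice) or a distribution tag:
#   {log_uniform: [lo, hi]}  - continuous, log scale
#   {uniform: [lo, hi]}      - continuous, linear scale
#   {int_uniform: [lo, hi]}  - integer, inclusive
version: 1

lightgbm:
  n_estimators: [50, 100, 200]
  num_leaves: [7, 15, 31]
  learning_rate: {log_uniform: [0.02, 0.2]}
  min_child_samples: [3, 5, 10]
  colsample_bytree: {uniform: [0.6, 1.0]}

lightgbm_xt:
  n_estimators: [50, 100, 200]
  num_leaves: [7, 15, 31]
  learning_rate: {log_uniform: [0.02, 0.2]}
  min_child_samples: [3, 5, 10]
  colsample_bytree: {uniform: [0.6, 1.0]}

lightgbm_large:
  n_estimators: [200, 400]
  num_leaves: [31, 63, 127]
  learning_rate: {log_uniform: [0.01, 0.1]}
  min_child_samples: [3, 5]
  colsample_bytree: {uniform: [0.6, 1.0]}

knn_uniform:
  n_neighbors: [3, 5, 7, 11, 15, 21]
  p: [1, 2]

knn_distance:
  n_neighbors: [3, 5, 7, 11, 15, 21]
  p: [1, 2]

mlp:
  hidden_units: [16, 32, 64]
  alpha: {log_uniform: [1.0e-5, 1.0e-2]}
  learning_rate_init: {log_uniform: [1.0e-3, 1.0e-2]}
  max_iter: [300, 600]

mlp_deep:
  hidden_units: [16, 32, 64]
  alpha: {log_uniform: [1.0e-5, 1.0e-2]}
  learning_rate_init: {log_uniform: [1.0e-3, 1.0e-2]}
  max_iter: [300, 600]

random_forest:
  n_estimators: [50, 100]
  max_features: [0.3, 0.5, 1.0, sqrt]
  min_samples_leaf: [1, 2, 5]

extra_trees:
  n_estimators: [50, 100]
  max_features: [0.3, 0.5, 1.0, sqrt]
  min_samples_leaf: [1, 2, 5]
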