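# Full study-protocol experiment on a synthetic study-scale cohort.
# Every omitted grid falls back to the default (full) search ranges.
cohort_spec:
  n_subjects: 314
  seed: 7
n_shuffles: 50
cv_folds: 10
models: [glm, lasso, elastic_net, gbdt, mlp]
seed: 1
background_size: 100
make_figures: true
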