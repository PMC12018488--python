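# End-to-end run on the built-in synthetic trial.
# `pragsub run --config examples/pipeline.yaml --seed 7`
simulation:
  n_subjects: 4600
  scenario: step_subgroups
estimator:
  n_trees: 200
  min_leaf: 20
max_depth: 2
min_leaf: 50
n_boot: 200
qini_scale: counts
propensity: 0.5
seed: 7
output_dir: pragsub_output
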