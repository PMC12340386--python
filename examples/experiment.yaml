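# Full-pipeline config for `rnflbase run --config examples/experiment.yaml`
# Stages: simulate -> prep -> train -> evaluate; artifacts + manifest under out_dir.
simulate:
  n_participants: 200
  two_eye_fraction: 0.68
  seed: 17
prep:
  target_ratio: 0.25
train:
  variants: [mag]        # any of: base, mag, reg (reg also trains the rCNN)
  seed: 7
  max_epochs: 60
evaluate:
  k: 2
  seed: 3
  models: [average, mlr, mag]
  max_epochs: 60
out_dir: runs/demo
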