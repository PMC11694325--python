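# Demo pipeline profile: a small synthetic reporting-system extract with one
# strongly planted drug-event association. Runs end to end in a few seconds:
#
#   pvdisprop run --config examples/demo_config.yaml --out runs/demo
generator:
  n_cases: 5000
  seed: 1
  duplicate_rate: 0.05
  invalid_age_rate: 0.005
  invalid_weight_rate: 0.005
  delete_rate: 0.005
  background_event_prob: 0.01
  fatal_prob: 0.297
  association:
    - [esomeprazole, Gastric cancer, 6.0]
    - [omeprazole, Renal cell carcinoma, 3.0]
scan:
  min_cases: 3
  z: 1.96
suspect_only: false
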