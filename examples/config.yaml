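# Full-pipeline run on a synthetic cohort at the study's scale.
# A real-data run would replace `synth:` with `manifest: path/to/manifest.json`.
synth:
  n_participants: 23
  tests_per_participant: 6
  seed: 1
  target_correlations:
    - [VM, Td, sit_up, 0.80]
alpha: 0.05
family_size: 12
descriptive_granularity: pooled
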