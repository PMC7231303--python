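# Demo run: 93 synthetic participants pushed through the epoch-level
# accelerometry reduction and all three analysis families.
seed: 7
out_dir: results/demo
generator:
  n_participants: 93
  outcome_noise_sd: 250.0
outcomes: [right_hippocampus, left_hippocampus]
analyses: {absolute: true, coda: true, pls: true}
stratify: true
simulate_epochs: true
epoch_seconds: 60
n_days: 7
pls_reps: 100
pls_holdout: 0.5
pls_k_max: 3
max_delta: 60.0
figures: true
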