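# Small end-to-end run: `glycorank all --config configs/example.yaml`
outdir: glycorank_run
seed: 42
simulation:
  n_patients: 2500
train_fraction: 0.8
split_by_patient: false
effects:
  bootstrap_b: 100
  propensity:
    max_epochs: 150
nma:
  n_warmup: 3000
  n_draws: 3000
ranking_draws: 2000
top_k: 3
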