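# Desk-scale run: every constant shrunk so the full pipeline finishes in
# about a minute on one CPU. Deleting a line falls back to the full-scale
# default for that field.
world:
  n_queries: 50
  pool_size_range: [3, 6]
  reliable_fraction: 0.8
  p_signal_given_reliable_assoc: 0.95
  vocab_size: 100
  article_length_range: [8, 20]
  rank_bias: 2.0
  seed: 7

classifier:
  embed_dim: 32
  hidden_dim: 64
  vocab_size: 104
  max_len: 40
  learning_rate: 0.01
  epochs: 8
  batch_size: 32

agent:
  learning_rate: 0.005
  replay_capacity: 4000
  epsilon_anneal_steps: 2000
  epsilon_end: 0.05
  target_sync_every: 100
  batch_size: 64

env:
  d_emb: 4

seed: 7
train_fraction: 0.8
agent_epochs: 25
steps_per_epoch: 10000
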