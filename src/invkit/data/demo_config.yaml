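# Demo pipeline: simulate the reciprocal capture experiment at a small scale
# and recover the subset share (~20% of INVs are ATG9A-flavor).
seed: 1
stages:
  - name: subset-share
    n_cells: 6
    n_seeds: 2
    image_shape: [320, 480]
  - name: pools
    max_loss: 71.5
    co_loss: 14.5
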