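# Fully-populated example configuration for `cellseg train` / `cellseg ablate`.
model:
  depth: 4
  base_channels: 16      # 64 reproduces the full-size canonical schedule
  variant: lr_ccf_fc     # baseline | ccf | fc | ccf_fc | lr_ccf_fc
  rank_L: 4              # rank-1 context vectors per direction
  heads_N: 4             # attention heads
  patch_size: 8          # stage-1 patch edge; halves per stage
  embed_dim: 64
  out_classes: 1
  in_channels: 1
  upsample: transposed   # or: nearest (nearest + 1x1 conv)
  fc_mode: gate          # or: add (element-wise alternative reading)
train:
  epochs: 40
  batch_size: 4
  learning_rate: 0.001
  optimizer: adam
  seed: 0
  augment: true          # random horizontal/vertical flips
  val_every: 1
  cosine_decay: false    # constant learning rate by default
  macro_average: false   # micro (pooled-pixel) metric aggregation
  loss:
    alpha: 0.5           # WCE/Dice blend weight
    beta: 1.0            # positive-class weight in the WCE
    epsilon: 1.0e-6      # Dice smoothing / log clamping
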