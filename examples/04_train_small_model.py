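"""Train a small full-variant model on a synthetic corpus.

Trains the low-rank cross-fusion variant for a few epochs on 32x32
images and prints the loss trajectory and validation metrics.  Scale
image_size/epochs/base_channels up for stronger results.
"""

from cellseg import ModelConfig, SyntheticSpec, TrainConfig, evaluate, generate, train

pairs = generate(SyntheticSpec(image_size=32, n_images=40, radius_min=4, radius_max=8, seed=1))
corpus = {"train": pairs[:32], "val": pairs[32:]}

model_cfg = ModelConfig(depth=3, base_channels=8, variant="lr_ccf_fc", patch_size=8)
train_cfg = TrainConfig(epochs=5, batch_size=4, learning_rate=1e-3, seed=0)

result = train(train_cfg, model_cfg, corpus, log=True)
row = evaluate(result.model, corpus["val"])
print("validation metrics after 5 epochs:")
for k, v in row.items():
    print(f"  {k:14s} {v:6.2f}")
# Dice/MIoU measure mask overlap; precision/recall split the error into
# false alarms vs missed cell pixels.
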