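"""Worked loss and metric values on hand-sized inputs.

Shows the weighted cross-entropy, the soft Dice loss, their alpha blend,
and the four evaluation metrics computed from explicit confusion counts.
"""

import numpy as np

from cellseg import (
    ConfusionCounts,
    LossConfig,
    combined_loss,
    confusion,
    dice_loss,
    metrics_row,
    weighted_cross_entropy,
)

p_hat = np.array([0.5])
p = np.array([1.0])
wce = weighted_cross_entropy(p_hat, p)
print(f"WCE(p=1, p_hat=0.5, beta=1) = {wce:.6f}   # -ln 0.5")

x = np.array([1.0, 1, 1, 1, 0, 0])
y = np.array([1.0, 1, 0, 0, 1, 1])
print(f"Dice loss, |X|=|Y|=4, |XnY|=2 = {dice_loss(x, y, 1e-12):.4f}   # 1 - 4/8")

blend = combined_loss(p_hat, p, LossConfig(alpha=0.5))
print(f"combined loss at alpha=0.5    = {blend:.6f}   # mean of WCE and Dice terms")

pred = np.array([[1, 0], [1, 0]])
true = np.array([[1, 1], [0, 0]])
c = confusion(pred, true)
print(f"confusion of the 4-pixel toy:  TP={c.tp} FP={c.fp} FN={c.fn} TN={c.tn}")
row = metrics_row(ConfusionCounts(13, 7, 5, 75))
print("metrics for TP=13 FP=7 FN=5 TN=75:")
for k, v in row.items():
    print(f"  {k:14s} {v:6.2f}")
# Dice is the harmonic mean of precision and recall; the IoU here is the
# single-foreground-class ratio TP/(TP+FP+FN).
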