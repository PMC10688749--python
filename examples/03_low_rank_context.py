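"""Rank-1 direction context vectors of a feature map.

Each encoder stage is summarised by 3L rank-1 vectors: L along each of
height, width and channel, obtained by global average pooling, a learned
1-D convolution, and a sigmoid.  These vectors carry cheap directional
context that the cross-fusion attention consumes.
"""

import numpy as np

from cellseg import SyntheticSpec, generate, generate_context

pair = generate(SyntheticSpec(image_size=64, n_images=1, seed=5))[0]
feature = pair.image[None]  # treat the raw image as a 1-channel feature map

ctx = generate_context(feature, L=4, rng=np.random.default_rng(0))
print(f"vectors per direction: L = {ctx.L};  total = {ctx.n_vectors} (3L)")
for d, v in ctx.vectors.items():
    print(f"  {d:8s} shape {v.shape}  range [{v.min():.3f}, {v.max():.3f}]")
# All entries lie in (0, 1) (post-sigmoid attention weights); the height
# vector length equals the image height, and so on per direction.
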