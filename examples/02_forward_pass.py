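"""Build the network and push one phantom through it.

Shows the token geometry of the U-shape: a 448x448 image becomes a 112x112
grid of 48-dim patch tokens, the encoder halves resolution twice (1/4 -> 1/8
-> 1/16 scale), and the decoder restores a full-resolution 2-class score map.
"""

import numpy as np

from vesselseg import ModelConfig, build_model, patch_partition
from vesselseg.phantom import PhantomSpec, generate_phantom

sample = generate_phantom(PhantomSpec(size=448, seed=3))

tokens = patch_partition(sample.image, patch=4)
print(f"patch partition: {sample.image.shape} -> {tokens.shape}")

# a narrow model keeps this demo quick on a laptop CPU; widen embed_dim for
# real training
cfg = ModelConfig(img_size=448, embed_dim=24, depths=(1, 1, 1), heads=(2, 4, 8))
model = build_model(cfg, seed=0)
F1, F2, F3 = model.encode(sample.image[None])
print(f"encoder pyramid: F1 {F1.shape}  F2 {F2.shape}  F3 {F3.shape}")

logits = model(sample.image[None])
print(f"class-score map: {logits.shape}")
probs = model.predict_proba(sample.image[None])[0]
print(f"mean vessel probability at init: {probs[..., 1].mean():.3f} "
      "(~0.5 before training, as expected from small random weights)")
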