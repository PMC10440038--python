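"""Walk one image pair through the architecture, stage by stage.

Shows the tensor shapes at each stage of the desk-scale model: CNN feature
map, bridged token sequence, adaptive modality weights, fused cls
embedding, and the final class probabilities.
"""

import numpy as np

from thyfuse import nn
from thyfuse.config import desk_scale_config
from thyfuse.data import prepare_pair
from thyfuse.model import build_variant, classify
from thyfuse.synthetic import generate_dataset, synthesize_irt_image, synthesize_us_image

cfg = desk_scale_config()
model = build_variant(cfg, seed=0)
spec = generate_dataset(1, 0, (0.0, 0.0, 1.0), seed=3).cases[0]
us, irt = prepare_pair(synthesize_us_image(spec), synthesize_irt_image(spec),
                       cfg.encoder.input_size)

model.eval()
with nn.no_grad():
    f_map = model.us_branch.backbone(nn.Tensor(us[None]))
    seq_us = model.us_branch(us[None])
    seq_irt = model.irt_branch(irt[None])
    weights = model.amwg(seq_us, seq_irt)
    fused = model.fuser(seq_us, seq_irt, weights)

print(f"input pair:        2 x {us.shape}")
print(f"CNN feature map:   {tuple(f_map.shape[1:])}  (C', H', W')")
print(f"token sequence:    {tuple(seq_us.tokens.shape[1:])}  (C'' tokens x H''W'' dims)")
print(f"modality weights:  w_us={weights.w_us[0]:.3f} w_irt={weights.w_irt[0]:.3f} "
      f"(sum {weights.w_us[0] + weights.w_irt[0]:.6f})")
print(f"fused cls embed:   {tuple(fused.shape[1:])}")

pred = classify(us, irt, model=model)
print(f"prediction (untrained net): {pred.predicted_label} "
      f"p=({pred.class_probs[0]:.3f}, {pred.class_probs[1]:.3f})")
print("an untrained network emits near-uniform probabilities; "
      "see 03_train_desk_scale.py for a trained one")
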