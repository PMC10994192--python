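"""Derivable tasks: class-activation heatmaps and the accept/exclude rule.

Trains a small abnormality classifier on X-ray-like phantoms, computes a
gradient class-activation map for an abnormal test image and checks that the
hottest pixel falls inside the lesion's bounding box; then exercises the
Doppler recommendation rule.
"""

import numpy as np

from umsrep import (ModalitySource, MultiTaskModel, PhantomConfig, PretrainConfig,
                    TaskSpec, build_supervised_backbone, generate_phantoms,
                    grad_cam, pretrain_supervised, recommend)
from umsrep.harness import adopt_pretraining_head

source = ModalitySource.from_samples(generate_phantoms(
    PhantomConfig(image_size=64, style="xray_like", n_samples=300,
                  abnormal_fraction=0.5, lesion_contrast=0.6, seed=0)))
model = build_supervised_backbone(widths=(8, 8, 16, 16, 16, 16), n_classes=2,
                                  input_size=64, fc_width=32, seed=0)
model, history = pretrain_supervised(model, source,
                                     cfg=PretrainConfig(loss="cce", optimizer="adam",
                                                        max_epochs=8, seed=0))
print(f"classifier validation accuracy: {history['val_accuracy'].iloc[-1]:.2f}")

mtm = MultiTaskModel(backbone=model)
adopt_pretraining_head(mtm, TaskSpec(name="abnormality", kind="classification",
                                     label_space=model.classes))

probe = next(s for s in generate_phantoms(
    PhantomConfig(image_size=64, style="xray_like", n_samples=10,
                  class_mix={"normal": 0.0, "abnormal": 1.0},
                  lesion_contrast=0.6, seed=1)))
amap = grad_cam(mtm, "abnormality", probe.clean_image)
r, c = np.unravel_index(int(amap.heatmap.argmax()), amap.heatmap.shape)
r0, c0, r1, c1 = probe.lesion_bbox
print(f"winning class: {amap.winning_class}; heatmap argmax ({r},{c}); "
      f"lesion box rows {r0}-{r1}, cols {c0}-{c1}; "
      f"inside: {r0 <= r < r1 and c0 <= c < c1}")
# the hottest pixel sitting inside the lesion box means the classifier's
# evidence is anatomically located, not a background shortcut.

print("\nrecommendation rule (target flow TR):")
for flow, quality in [("TR", "good"), ("TR", "low"), ("MV", "good")]:
    rec = recommend(flow, quality, "TR")
    print(f"  flow={flow:>2} quality={quality:<4} -> {rec.decision}: {rec.reason}")
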