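"""Derivable tasks: gradient class-activation heatmaps and rule-based recommendation.

Derivable tasks consume trained task heads instead of training anything new.
The heatmap follows the gradient-CAM recipe: gradients of the winning
class's pre-softmax score with respect to the deepest convolutional feature
map are averaged per channel into weights, the weighted channel sum is
rectified (negative evidence zeroed), min-max normalized to [0, 1]
(an all-constant map maps to all zeros) and bilinearly upsampled to the
input resolution.  Normalization happens before upsampling.

The recommendation rule merges a flow-classification and a quality head:
an image is accepted for downstream measurement only when it shows the
requested flow at good quality; otherwise it is excluded with a reason
naming the failed condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .multitask import FinetuneError, MultiTaskModel
from .phantom_data import QUALITY_LABELS


@dataclass
class ActivationMap:
    heatmap: np.ndarray                  # (H, W) in [0, 1] at input resolution
    winning_class: str
    raw_map_size: tuple[int, int]


@dataclass
class Recommendation:
    decision: str                        # "accept" | "exclude"
    reason: str


def grad_cam(model: MultiTaskModel, task_name: str, image: np.ndarray) -> ActivationMap:
    """Class-activation heatmap for one (preprocessed-scale) grayscale image."""
    head = model.head(task_name)
    if head.task.kind != "classification":
        raise FinetuneError("grad_cam needs a classification head")
    x = model.backbone.prepare(image[None])
    feat = model.encoder().forward(x, training=False)        # (1, C, h, w)
    probs = head.net.forward(feat, training=False)
    win = int(probs[0].argmax())

    # gradient of the winning pre-softmax score w.r.t. the feature map
    onehot = np.zeros_like(probs)
    onehot[0, win] = 1.0
    dfeat = head.net.backward_from(onehot, len(head.net.layers) - 1)

    alpha = dfeat[0].mean(axis=(1, 2))                        # (C,)
    cam = np.tensordot(alpha, feat[0], axes=([0], [0]))       # (h, w)
    cam = np.maximum(cam, 0.0)
    span = cam.max() - cam.min()
    cam = np.zeros_like(cam) if span == 0 else (cam - cam.min()) / span
    heat = _sk_resize(cam, image.shape, order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)
    return ActivationMap(heatmap=np.clip(heat, 0.0, 1.0).astype(np.float32),
                         winning_class=head.task.label_space[win],
                         raw_map_size=cam.shape)


def overlay_heatmap(image: np.ndarray, heatmap: np.ndarray,
                    alpha: float = 0.5, cmap: str = "jet") -> np.ndarray:
    """Blend a heatmap over a grayscale image; returns (H, W, 3) in [0, 1]."""
    import matplotlib

    colour = matplotlib.colormaps[cmap](heatmap)[..., :3]
    grey = np.repeat(np.clip(image, 0, 1)[..., None], 3, axis=2)
    return (1 - alpha) * grey + alpha * colour


def recommend(flow_prediction: str, quality_prediction: str,
              target_flow: str, flow_labels=("TR", "MV", "MA")) -> Recommendation:
    """Accept an image iff it shows the target flow at good quality."""
    if flow_prediction not in flow_labels or target_flow not in flow_labels:
        raise ValueError(f"flow labels must come from {flow_labels}")
    if quality_prediction not in QUALITY_LABELS:
        raise ValueError(f"quality labels must come from {QUALITY_LABELS}")
    if flow_prediction != target_flow:
        return Recommendation(
            decision="exclude",
            reason=f"flow is {flow_prediction}, not the requested {target_flow}")
    if quality_prediction != "good":
        return Recommendation(decision="exclude",
                              reason=f"{target_flow} image is low quality")
    return Recommendation(decision="accept",
                          reason=f"good-quality {target_flow} image")
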