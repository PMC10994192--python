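"""Training losses as (value, gradient) pairs.

These operate on network *outputs* (post-sigmoid probabilities or
post-softmax class distributions) and return the gradient with respect to
those outputs, which is then chained through the output nonlinearity by the
network's backward pass.  Values agree with the scalar metric functions in
``umsrep.metrics_losses`` (asserted in the test suite).
"""

from __future__ import annotations

import numpy as np

EPSILON = 1e-7


def mse_vg(y: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over every element; used for denoising pretraining."""
    d = y - t
    return float(np.mean(d.astype(np.float64) ** 2)), (2.0 / d.size) * d


def cce_vg(y: np.ndarray, t: np.ndarray, eps: float = EPSILON) -> tuple[float, np.ndarray]:
    """Categorical cross-entropy, mean over the batch.

    ``y``: (N, C) class probabilities, ``t``: (N, C) one-hot targets.
    """
    yc = np.clip(y, eps, 1.0 - eps)
    n = y.shape[0]
    value = float(-(t * np.log(yc.astype(np.float64))).sum() / n)
    grad = np.where((y > eps) & (y < 1.0 - eps), -t / yc, 0.0) / n
    return value, grad.astype(y.dtype)


def _per_sample_flat(a: np.ndarray) -> np.ndarray:
    return a.reshape(a.shape[0], -1)


def combined_seg_vg(y: np.ndarray, t: np.ndarray, w1: float = 0.5, w2: float = 0.5,
                    eps: float = EPSILON) -> tuple[float, np.ndarray]:
    """Weighted BCE + Dice segmentation loss, averaged over the mini-batches of a batch.

    Each sample in the leading axis is one mini-batch term; the batch loss is
    the mean of the per-sample ``w1*BCE + w2*Dice`` values.  ``y`` holds
    per-pixel foreground probabilities, ``t`` binary masks of the same shape.
    """
    yf = _per_sample_flat(y)
    tf_ = _per_sample_flat(t).astype(np.float64)
    n, p = yf.shape
    yc = np.clip(yf.astype(np.float64), eps, 1.0 - eps)

    bce = -(tf_ * np.log(yc) + (1.0 - tf_) * np.log(1.0 - yc)).mean(axis=1)
    in_range = (yf > eps) & (yf < 1.0 - eps)
    g_bce = np.where(in_range, (yc - tf_) / (yc * (1.0 - yc)), 0.0) / p

    s_t = tf_.sum(axis=1)
    s_y = yf.astype(np.float64).sum(axis=1)
    inter = (tf_ * yf).sum(axis=1)
    denom = s_t + s_y
    safe = denom > 0
    dice = np.where(safe, 1.0 - 2.0 * inter / np.where(safe, denom, 1.0), 0.0)
    # d/dy_j [1 - 2*I/D] = -(2*t_j*D - 2*I) / D^2
    g_dice = np.where(safe[:, None],
                      -(2.0 * tf_ * denom[:, None] - 2.0 * inter[:, None])
                      / np.where(safe, denom, 1.0)[:, None] ** 2,
                      0.0)

    value = float(np.mean(w1 * bce + w2 * dice))
    grad = ((w1 * g_bce + w2 * g_dice) / n).reshape(y.shape)
    return value, grad.astype(y.dtype)
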