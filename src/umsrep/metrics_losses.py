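"""Losses, image-quality metrics, classification/segmentation metrics, McNemar test.

Conventions adopted where the field leaves a free choice:

* The binary cross-entropy is the standard negative log-likelihood (mean over
  pixels), so it is non-negative and minimized when prediction equals target.
* Empty-vs-empty masks: Dice loss 0 and IoU 1, so perfect agreement is never
  penalized.
* Probabilities are clamped to ``[eps, 1-eps]`` with ``eps = 1e-7`` before
  logarithms.
* SSIM uses the standard 11-tap Gaussian window (sigma 1.5) with
  ``C1=(0.01 L)^2``, ``C2=(0.03 L)^2`` and population (window-weighted)
  moments; MS-SSIM uses dyadic 2x2 mean downsampling with the canonical
  five-scale exponent weights (renormalized when fewer scales fit the image).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d
from scipy.stats import binomtest, chi2

EPSILON = 1e-7

MS_SSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


class MetricError(ValueError):
    pass


@dataclass
class CombinedLossConfig:
    """Weights for the compound segmentation loss ``w1*BCE + w2*Dice``."""
    w1: float = 0.5
    w2: float = 0.5
    epsilon: float = EPSILON

    def __post_init__(self):
        if self.w1 < 0 or self.w2 < 0:
            raise MetricError("loss weights must be non-negative")
        if not 0.0 < self.epsilon <= 0.01:
            raise MetricError("epsilon must lie in (0, 0.01]")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise MetricError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _check_shapes(t, y):
    t, y = np.asarray(t), np.asarray(y)
    if t.shape != y.shape:
        raise MetricError(f"shape mismatch: {t.shape} vs {y.shape}")
    return t, y


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def bce_loss(t, y, epsilon: float = EPSILON) -> float:
    """Mean binary cross-entropy between a {0,1} target and a probability map."""
    t, y = _check_shapes(t, y)
    yc = np.clip(y.astype(np.float64), epsilon, 1.0 - epsilon)
    t = t.astype(np.float64)
    return float(-np.mean(t * np.log(yc) + (1.0 - t) * np.log(1.0 - yc)))


def dice_loss(t, y) -> float:
    """``1 - 2|t.y| / (|t| + |y|)``; 0 when both inputs are all-zero."""
    t, y = _check_shapes(t, y)
    t, y = t.astype(np.float64), y.astype(np.float64)
    denom = t.sum() + y.sum()
    if denom == 0:
        return 0.0
    return float(1.0 - 2.0 * (t * y).sum() / denom)


def combined_seg_loss(t, y, cfg: CombinedLossConfig | None = None) -> float:
    """Compound segmentation loss, averaged over the mini-batches of a batch.

    2-D inputs are a single mini-batch term; with a leading batch axis each
    sample contributes one ``w1*BCE + w2*Dice`` term and the mean is returned.
    """
    cfg = cfg or CombinedLossConfig()
    t, y = _check_shapes(t, y)
    if t.ndim <= 2:
        t, y = t[None], y[None]
    terms = [cfg.w1 * bce_loss(ti, yi, cfg.epsilon) + cfg.w2 * dice_loss(ti, yi)
             for ti, yi in zip(t, y)]
    return float(np.mean(terms))


def cce_loss(t, y, epsilon: float = EPSILON) -> float:
    """Categorical cross-entropy ``-sum t_c log y_c`` for one prediction."""
    t, y = _check_shapes(t, y)
    if not math.isclose(float(np.sum(y)), 1.0, abs_tol=1e-6):
        raise MetricError("probabilities must sum to 1")
    yc = np.clip(y.astype(np.float64), epsilon, 1.0 - epsilon)
    return float(-(t * np.log(yc)).sum())


# ---------------------------------------------------------------------------
# Image-quality metrics
# ---------------------------------------------------------------------------

def psnr(ref, test, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the images are identical."""
    ref, test = _check_shapes(ref, test)
    if data_range <= 0:
        raise MetricError("data_range must be positive")
    mse = float(np.mean((ref.astype(np.float64) - test.astype(np.float64)) ** 2))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(data_range ** 2 / mse))


def _gaussian_window(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    r = size // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    w = np.exp(-(x ** 2) / (2.0 * sigma ** 2))
    return w / w.sum()


def _filter_valid(img: np.ndarray, w: np.ndarray) -> np.ndarray:
    r = len(w) // 2
    out = convolve1d(convolve1d(img, w, axis=0, mode="constant"), w, axis=1, mode="constant")
    return out[r:-r, r:-r]


def _ssim_maps(ref, test, data_range, win_size=11, sigma=1.5):
    w = _gaussian_window(win_size, sigma)
    x = np.asarray(ref, dtype=np.float64)
    y = np.asarray(test, dtype=np.float64)
    mx, my = _filter_valid(x, w), _filter_valid(y, w)
    sxx = _filter_valid(x * x, w) - mx * mx
    syy = _filter_valid(y * y, w) - my * my
    sxy = _filter_valid(x * y, w) - mx * my
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    lum = (2 * mx * my + c1) / (mx ** 2 + my ** 2 + c1)
    cs = (2 * sxy + c2) / (sxx + syy + c2)
    return lum, cs


def ssim(ref, test, data_range: float = 1.0, win_size: int = 11, sigma: float = 1.5) -> float:
    """Windowed structural similarity (Gaussian window, population moments)."""
    ref, test = _check_shapes(ref, test)
    if min(ref.shape) < win_size:
        raise MetricError(f"image smaller than the {win_size}x{win_size} SSIM window")
    lum, cs = _ssim_maps(ref, test, data_range, win_size, sigma)
    return float(np.mean(lum * cs))


def _downsample2(img: np.ndarray) -> np.ndarray:
    h, w = (img.shape[0] // 2) * 2, (img.shape[1] // 2) * 2
    img = img[:h, :w]
    return img.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))


def ms_ssim(ref, test, data_range: float = 1.0, n_scales: int = 5,
            win_size: int = 11, sigma: float = 1.5) -> float:
    """Multi-scale SSIM over dyadic scales.

    Contrast/structure terms enter at every scale, luminance only at the
    coarsest; weights are the canonical five-scale exponents, renormalized
    when ``n_scales < 5``.  Raises when the coarsest scale would fall below
    the window size.
    """
    ref, test = _check_shapes(ref, test)
    if not 1 <= n_scales <= 5:
        raise MetricError("n_scales must be in 1..5")
    if min(ref.shape) // (2 ** (n_scales - 1)) < win_size:
        raise MetricError(f"image too small for a {n_scales}-scale pyramid "
                          f"with a {win_size}-pixel window")
    weights = np.array(MS_SSIM_WEIGHTS[:n_scales], dtype=np.float64)
    weights = weights / weights.sum()
    x, y = np.asarray(ref, np.float64), np.asarray(test, np.float64)
    value = 1.0
    for s in range(n_scales):
        lum, cs = _ssim_maps(x, y, data_range, win_size, sigma)
        if s < n_scales - 1:
            value *= max(float(np.mean(cs)), 0.0) ** weights[s]
            x, y = _downsample2(x), _downsample2(y)
        else:
            value *= max(float(np.mean(lum * cs)), 0.0) ** weights[s]
    return float(value)


# ---------------------------------------------------------------------------
# Classification / segmentation metrics
# ---------------------------------------------------------------------------

def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, F-score and Matthews correlation from binary confusion counts."""
    if c.total == 0:
        raise MetricError("empty confusion matrix")
    accuracy = (c.tp + c.tn) / c.total
    f_denom = 2 * c.tp + c.fp + c.fn
    f_score = 2 * c.tp / f_denom if f_denom else 0.0
    factors = [(c.tp + c.fp), (c.tp + c.fn), (c.tn + c.fp), (c.tn + c.fn)]
    if 0 in factors:
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(math.prod(float(f) for f in factors))
    return {"accuracy": float(accuracy), "f_score": float(f_score), "mcc": float(mcc)}


def confusion_from_labels(y_true, y_pred, positive) -> ConfusionCounts:
    """Binary confusion counts treating ``positive`` as the positive class."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def iou(mask_a, mask_b) -> float:
    """Intersection over union of two binary masks; 1 when both are empty."""
    a, b = _check_shapes(mask_a, mask_b)
    a, b = a.astype(bool), b.astype(bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def dice_coefficient(mask_a, mask_b) -> float:
    """``2|A.B| / (|A| + |B|)`` on binary masks; equals ``2 IoU / (1 + IoU)``."""
    return 1.0 - dice_loss(np.asarray(mask_a, dtype=float), np.asarray(mask_b, dtype=float))


# ---------------------------------------------------------------------------
# Paired significance test
# ---------------------------------------------------------------------------

def mcnemar_test(b: int, c: int, exact_threshold: int = 25) -> float:
    """McNemar's test on discordant pair counts.

    ``b``: cases only model 1 got right, ``c``: cases only model 2 got right.
    Exact two-sided binomial when ``b + c < exact_threshold``; otherwise the
    chi-square approximation with continuity correction
    ``(|b - c| - 1)^2 / (b + c)`` on 1 df.  ``b + c = 0`` gives p = 1.
    """
    if b < 0 or c < 0:
        raise MetricError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    if n < exact_threshold:
        return float(binomtest(min(b, c), n, 0.5, alternative="two-sided").pvalue)
    stat = (abs(b - c) - 1) ** 2 / n
    return float(chi2.sf(stat, df=1))
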