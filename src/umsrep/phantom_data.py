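"""Seeded synthetic phantom images with ground-truth masks and labels.

Two desk-scale image families stand in for the real modalities:

* ``xray_like`` — two bright ellipses ("lungs") on a dim background; their
  union is the segmentation mask.  Abnormal classes add lesion discs inside
  a lung: one large focal disc for ``abnormal``/``bacterial``, several small
  discs for ``viral``.
* ``doppler_like`` — a half-period spectral envelope filled below a bright
  baseline; the filled region is the mask.  The flow classes TR/MV/MA differ
  in envelope peak height and width.

Geometry parameters are jittered uniformly within +-15% of their class means
so that classes are separable but not trivial.  Class and quality counts
follow a deterministic largest-remainder allocation, and the whole generator
is a pure function of its configuration (including the seed).

Noise is parameterized on the 0-255 intensity scale even though images are
stored in [0, 1]: Gaussian noise adds zero-mean draws of standard deviation
``sigma`` on that scale; Poisson noise replaces each pixel by a draw with
mean ``pixel * 255`` (so the local variance equals the mean — the
``mu = sigma^2`` convention) scaled back to [0, 1].  Values are clipped to
the physical intensity bounds after corruption.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

XRAY_CLASSES_2 = ("normal", "abnormal")
XRAY_CLASSES_3 = ("normal", "bacterial", "viral")
DOPPLER_CLASSES = ("TR", "MV", "MA")
QUALITY_LABELS = ("good", "low")

JITTER = 0.15  # relative half-width of the uniform geometry jitter


class PhantomConfigError(ValueError):
    pass


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model on the 0-255 intensity scale.

    ``kind='poisson'`` draws have variance equal to their mean, so a region
    of mean intensity ``mu`` behaves like Gaussian noise of ``sigma =
    sqrt(mu)`` (the ``mu = sigma^2`` parameterization); ``sigma`` is ignored
    for Poisson and ``none``.
    """
    kind: str = "none"
    sigma: float = 0.0

    def __post_init__(self):
        if self.kind not in ("gaussian", "poisson", "none"):
            raise PhantomConfigError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise PhantomConfigError("sigma must be non-negative")


@dataclass(frozen=True)
class PhantomConfig:
    image_size: int = 64
    style: str = "xray_like"
    n_samples: int = 100
    class_mix: dict[str, float] | None = None
    abnormal_fraction: float | None = None
    lesion_contrast: float = 0.35
    low_quality_fraction: float = 0.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 16:
            raise PhantomConfigError("image_size must be >= 16")
        if self.style not in ("xray_like", "doppler_like"):
            raise PhantomConfigError(f"unknown style {self.style!r}")
        if self.n_samples < 0:
            raise PhantomConfigError("n_samples must be >= 0")
        if not 0.0 <= self.low_quality_fraction <= 1.0:
            raise PhantomConfigError("low_quality_fraction must lie in [0, 1]")
        if not 0.0 <= self.lesion_contrast <= 1.0:
            raise PhantomConfigError("lesion_contrast must lie in [0, 1]")
        if self.abnormal_fraction is not None:
            if not 0.0 <= self.abnormal_fraction <= 1.0:
                raise PhantomConfigError("abnormal_fraction must lie in [0, 1]")
            if self.class_mix is not None:
                raise PhantomConfigError("give class_mix or abnormal_fraction, not both")

    def resolved_mix(self) -> dict[str, float]:
        if self.abnormal_fraction is not None:
            mix = {"normal": 1.0 - self.abnormal_fraction,
                   "abnormal": self.abnormal_fraction}
        elif self.class_mix is not None:
            mix = dict(self.class_mix)
        elif self.style == "xray_like":
            mix = {"normal": 0.5, "abnormal": 0.5}
        else:
            # default flow mix mirrors the reference Doppler corpus proportions
            mix = {"TR": 0.45, "MV": 0.35, "MA": 0.20}
        labels = self.label_space()
        for k in mix:
            if k not in labels:
                raise PhantomConfigError(f"label {k!r} not in label space {labels}")
        if any(v < 0 for v in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-9:
            raise PhantomConfigError("class_mix must be non-negative and sum to 1")
        return mix

    def label_space(self) -> tuple[str, ...]:
        if self.style == "doppler_like":
            return DOPPLER_CLASSES
        if self.class_mix is not None and any(k in self.class_mix for k in ("bacterial", "viral")):
            return XRAY_CLASSES_3
        return XRAY_CLASSES_2


@dataclass
class PhantomSample:
    image: np.ndarray        # (H, W) float32 in [0, 1], possibly noisy/degraded
    mask: np.ndarray         # (H, W) uint8 in {0, 1}
    class_label: str
    quality_label: str
    clean_image: np.ndarray  # noise-free, non-degraded counterpart
    seed_id: int
    lesion_bbox: tuple[int, int, int, int] | None = None  # (r0, c0, r1, c1), inclusive-exclusive


def largest_remainder_counts(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Integer allocation of ``n`` by fractions; deterministic tie-breaking.

    Floors every quota, then hands remaining units to the largest fractional
    remainders (declaration order breaks ties).
    """
    keys = list(fractions)
    quotas = np.array([n * fractions[k] for k in keys], dtype=np.float64)
    counts = np.floor(quotas + 1e-9).astype(int)
    short = n - counts.sum()
    remainders = quotas - counts
    order = sorted(range(len(keys)), key=lambda i: (-remainders[i], i))
    for i in order[:short]:
        counts[i] += 1
    return dict(zip(keys, counts.tolist()))


def add_noise(image: np.ndarray, spec: NoiseSpec, seed: int) -> np.ndarray:
    """Corrupt a [0, 1] image per ``spec``; pure in (image, spec, seed)."""
    image = np.asarray(image, dtype=np.float32)
    if image.min() < 0 or image.max() > 1:
        raise PhantomConfigError("image values must lie in [0, 1]")
    if spec.kind == "none":
        return image.copy()
    rng = np.random.default_rng(seed)
    scaled = image.astype(np.float64) * 255.0
    if spec.kind == "gaussian":
        noisy = scaled + rng.normal(0.0, spec.sigma, image.shape)
    else:  # poisson: each pixel becomes a draw with mean (= variance) pixel*255
        noisy = rng.poisson(scaled).astype(np.float64)
    return (np.clip(noisy, 0.0, 255.0) / 255.0).astype(np.float32)


def _jitter(rng, mean):
    return mean * rng.uniform(1.0 - JITTER, 1.0 + JITTER)


def _ellipse_mask(size, cy, cx, ay, ax):
    yy, xx = np.mgrid[0:size, 0:size]
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _disc_mask(size, cy, cx, r):
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2


def _bbox(mask) -> tuple[int, int, int, int]:
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    return int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1


def _xray_phantom(rng, size, class_label, lesion_contrast):
    img = np.full((size, size), 0.12, dtype=np.float64)
    img += 0.03 * gaussian_filter(rng.standard_normal((size, size)), sigma=size / 8)
    mask = np.zeros((size, size), dtype=bool)
    lungs = []
    for side in (-1, +1):
        cy = _jitter(rng, 0.52 * size)
        cx = 0.5 * size + side * _jitter(rng, 0.22 * size)
        ay = _jitter(rng, 0.30 * size)
        ax = _jitter(rng, 0.15 * size)
        lungs.append((cy, cx, ay, ax))
        ell = _ellipse_mask(size, cy, cx, ay, ax)
        mask |= ell
        img[ell] = 0.50 + 0.04 * rng.standard_normal()
    lesion = np.zeros((size, size), dtype=bool)
    if class_label in ("abnormal", "bacterial"):
        lesion |= _place_lesion(rng, size, lungs, radius=_jitter(rng, 0.075 * size))
    elif class_label == "viral":
        for _ in range(3):
            lesion |= _place_lesion(rng, size, lungs, radius=_jitter(rng, 0.040 * size))
    img[lesion] += lesion_contrast
    bbox = _bbox(lesion) if lesion.any() else None
    img = np.clip(img, 0.0, 1.0)
    return img, mask, bbox


def _place_lesion(rng, size, lungs, radius):
    """A disc guaranteed to lie inside one of the lung ellipses."""
    cy, cx, ay, ax = lungs[rng.integers(len(lungs))]
    margin = 1.2 * radius
    ay_in, ax_in = max(ay - margin, 0.5), max(ax - margin, 0.5)
    theta = rng.uniform(0, 2 * np.pi)
    rho = np.sqrt(rng.uniform())
    return _disc_mask(size, cy + rho * np.sin(theta) * ay_in,
                      cx + rho * np.cos(theta) * ax_in, radius)


# class-mean envelope parameters (fractions of the image side)
_DOPPLER_PARAMS = {"TR": (0.60, 0.72), "MV": (0.38, 0.55), "MA": (0.22, 0.42)}


def _doppler_phantom(rng, size, class_label):
    peak_f, width_f = _DOPPLER_PARAMS[class_label]
    peak = _jitter(rng, peak_f * size)
    width = min(_jitter(rng, width_f * size), size - 2)
    baseline = int(round(0.20 * size))
    x0 = rng.uniform(0, size - width)
    img = np.full((size, size), 0.06, dtype=np.float64)
    img += 0.02 * np.abs(rng.standard_normal((size, size)))
    cols = np.arange(size)
    phase = (cols - x0) / width
    height = np.where((phase >= 0) & (phase <= 1),
                      peak * np.sin(np.pi * np.clip(phase, 0, 1)), 0.0)
    yy = np.arange(size)[:, None]
    fill = (yy > baseline) & (yy <= baseline + height[None, :])
    img[fill] = 0.70 + 0.05 * rng.standard_normal()
    img[baseline - 1:baseline + 1, :] = 0.9  # bright zero-velocity line
    img = np.clip(img, 0.0, 1.0)
    return img, fill


def _degrade(rng, img, size):
    """Low-quality rendition: blur plus multiplicative speckle."""
    blurred = gaussian_filter(img, sigma=0.03 * size)
    speckled = blurred * (1.0 + 0.25 * rng.standard_normal(img.shape))
    return np.clip(speckled, 0.0, 1.0)


def generate_phantoms(config: PhantomConfig) -> list[PhantomSample]:
    """Generate ``config.n_samples`` seeded phantoms with exact class counts."""
    mix = config.resolved_mix()
    counts = largest_remainder_counts(config.n_samples, mix)
    labels = [lab for lab, c in counts.items() for _ in range(c)]
    q_counts = largest_remainder_counts(
        config.n_samples, {"low": config.low_quality_fraction,
                           "good": 1.0 - config.low_quality_fraction})
    qualities = ["low"] * q_counts["low"] + ["good"] * q_counts["good"]

    order_rng = np.random.default_rng([config.seed, 0xA5])
    labels = [labels[i] for i in order_rng.permutation(len(labels))]
    qualities = [qualities[i] for i in order_rng.permutation(len(qualities))]

    samples = []
    for i, (label, quality) in enumerate(zip(labels, qualities)):
        rng = np.random.default_rng([config.seed, 1, i])
        if config.style == "xray_like":
            clean, mask, bbox = _xray_phantom(rng, config.image_size, label,
                                              config.lesion_contrast)
        else:
            clean, mask = _doppler_phantom(rng, config.image_size, label)
            bbox = None
        if quality == "low":
            clean = _degrade(rng, clean, config.image_size)
        clean = clean.astype(np.float32)
        image = add_noise(clean, config.noise, seed=int(rng.integers(2**31)))
        samples.append(PhantomSample(image=image, mask=mask.astype(np.uint8),
                                     class_label=label, quality_label=quality,
                                     clean_image=clean, seed_id=i, lesion_bbox=bbox))
    return samples


# ---------------------------------------------------------------------------
# Disk round-trip
# ---------------------------------------------------------------------------

def _to_u8(img: np.ndarray) -> np.ndarray:
    return np.round(np.clip(img, 0, 1) * 255).astype(np.uint8)


def save_phantoms(samples: list[PhantomSample], out_dir,
                  split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15)) -> Path:
    """Write 8-bit PNGs plus a manifest; returns the manifest path.

    Split assignment follows the (already shuffled) sample order with a
    largest-remainder allocation over (train, val, test).
    """
    out = Path(out_dir)
    for sub in ("images", "masks", "clean"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    counts = largest_remainder_counts(len(samples), dict(zip(
        ("train", "val", "test"), split_fractions)))
    splits = (["train"] * counts["train"] + ["val"] * counts["val"]
              + ["test"] * counts["test"])
    rows = []
    for s, split in zip(samples, splits):
        name = f"{s.seed_id:05d}.png"
        Image.fromarray(_to_u8(s.image)).save(out / "images" / name)
        Image.fromarray(_to_u8(s.clean_image)).save(out / "clean" / name)
        Image.fromarray((s.mask * 255).astype(np.uint8)).save(out / "masks" / name)
        rows.append({"path": f"images/{name}", "split": split,
                     "class_label": s.class_label, "quality_label": s.quality_label,
                     "mask_path": f"masks/{name}", "clean_path": f"clean/{name}",
                     "seed_id": s.seed_id})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
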