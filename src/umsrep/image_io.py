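"""Reading/writing images and manifests, preprocessing, the modality-source container.

Preprocessing follows the reference pipeline: bicubic resampling to a square
target size followed by mean normalization.  The bicubic kernel is the
Catmull-Rom cubic (a = -0.5) evaluated at half-pixel-centred sample
positions with edge clamping — one fixed dialect so results are
bit-reproducible.  "Mean normalization" subtracts a single scalar mean
computed from the training split (no variance scaling); a per-image variant
is available behind a flag.  The fitted normalizer is stored on the source
so validation/test data reuse the training statistic (no leakage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .phantom_data import PhantomSample, largest_remainder_counts

SPLITS = ("train", "val", "test")


class ManifestError(ValueError):
    pass


@dataclass
class ManifestRecord:
    path: str
    split: str
    class_label: str | None = None
    quality_label: str | None = None
    mask_path: str | None = None
    clean_path: str | None = None
    seed_id: int | None = None

    def __post_init__(self):
        if self.split not in SPLITS:
            raise ManifestError(f"unknown split {self.split!r} for {self.path!r}")


# ---------------------------------------------------------------------------
# Bicubic resize (Catmull-Rom, half-pixel centers, clamped edges)
# ---------------------------------------------------------------------------

def _cubic(x: np.ndarray, a: float = -0.5) -> np.ndarray:
    x = np.abs(x)
    out = np.zeros_like(x)
    m1 = x <= 1
    m2 = (x > 1) & (x < 2)
    out[m1] = ((a + 2) * x[m1] - (a + 3)) * x[m1] ** 2 + 1
    out[m2] = a * (((x[m2] - 5) * x[m2] + 8) * x[m2] - 4)
    return out


def _resize_matrix(n_in: int, n_out: int, a: float = -0.5) -> np.ndarray:
    """Dense (n_out, n_in) row-stochastic interpolation matrix for one axis."""
    W = np.zeros((n_out, n_in), dtype=np.float64)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        base = int(np.floor(src))
        for m in range(-1, 3):
            j = base + m
            w = float(_cubic(np.array([src - j]), a)[0])
            W[i, min(max(j, 0), n_in - 1)] += w
    return W


def resize_bicubic(image: np.ndarray, target_size: int) -> np.ndarray:
    """Separable Catmull-Rom bicubic resample of a 2-D image to a square grid."""
    if target_size < 8:
        raise ValueError("target_size must be >= 8")
    image = np.asarray(image, dtype=np.float64)
    if image.shape == (target_size, target_size):
        return image.astype(np.float32)
    wr = _resize_matrix(image.shape[0], target_size)
    wc = _resize_matrix(image.shape[1], target_size)
    return (wr @ image @ wc.T).astype(np.float32)


class MeanNormalizer:
    """Scalar mean subtraction fitted on the training split.

    ``per_image=True`` instead centres every image on its own mean (then
    ``fit`` is a no-op kept for interface symmetry).
    """

    def __init__(self, per_image: bool = False):
        self.per_image = per_image
        self.mean_: float | None = None

    def fit(self, images: np.ndarray) -> "MeanNormalizer":
        images = np.asarray(images)
        if images.size == 0:
            raise ValueError("cannot fit a normalizer on an empty split")
        self.mean_ = float(images.mean())
        return self

    def transform(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=np.float32)
        if self.per_image:
            axes = tuple(range(image.ndim - 2, image.ndim))
            return image - image.mean(axis=axes, keepdims=True)
        if self.mean_ is None:
            raise ValueError("normalizer is not fitted")
        return image - np.float32(self.mean_)

    def to_dict(self) -> dict:
        return {"per_image": self.per_image, "mean": self.mean_}

    @classmethod
    def from_dict(cls, d: dict) -> "MeanNormalizer":
        norm = cls(per_image=d["per_image"])
        norm.mean_ = d["mean"]
        return norm


def preprocess(image: np.ndarray, target_size: int,
               normalizer: MeanNormalizer | None = None) -> np.ndarray:
    """Bicubic resize to ``target_size`` then (optionally) mean normalization."""
    resized = resize_bicubic(image, target_size)
    if normalizer is None:
        return resized
    return normalizer.transform(resized)


# ---------------------------------------------------------------------------
# Modality source
# ---------------------------------------------------------------------------

@dataclass
class ModalitySource:
    """A named dataset for one imaging modality, split into train/val/test.

    Holds decoded [0, 1] images, optional binary masks and noise-free
    counterparts, plus the per-pixel summary statistics used for
    normalization.
    """

    name: str
    frame: pd.DataFrame
    images: np.ndarray                      # (N, H, W) float32 in [0, 1]
    masks: np.ndarray | None = None         # (N, H, W) uint8 in {0, 1}
    clean: np.ndarray | None = None         # (N, H, W) float32
    normalizer: MeanNormalizer = field(default_factory=MeanNormalizer)

    def __post_init__(self):
        bad = set(self.frame["split"]) - set(SPLITS)
        if bad:
            raise ManifestError(f"unknown splits {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def image_size(self) -> int:
        return self.images.shape[1]

    def indices(self, split: str) -> np.ndarray:
        return np.flatnonzero((self.frame["split"] == split).to_numpy())

    def images_for(self, split: str) -> np.ndarray:
        return self.images[self.indices(split)]

    def clean_for(self, split: str) -> np.ndarray:
        src = self.clean if self.clean is not None else self.images
        return src[self.indices(split)]

    def masks_for(self, split: str) -> np.ndarray:
        if self.masks is None:
            raise ManifestError(f"source {self.name!r} has no masks")
        return self.masks[self.indices(split)]

    def labels_for(self, split: str, column: str = "class_label") -> np.ndarray:
        return self.frame.loc[self.indices(split), column].to_numpy()

    def empirical_distribution(self) -> dict[str, float]:
        train = self.images_for("train")
        return {"mean": float(train.mean()), "std": float(train.std())}

    def fit_normalizer(self) -> MeanNormalizer:
        self.normalizer.fit(self.images_for("train"))
        return self.normalizer

    @classmethod
    def from_samples(cls, samples: list[PhantomSample], name: str = "phantom",
                     split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
                     ) -> "ModalitySource":
        """Build an in-memory source straight from generated phantoms."""
        counts = largest_remainder_counts(len(samples), dict(zip(SPLITS, split_fractions)))
        splits = [s for s in SPLITS for _ in range(counts[s])]
        frame = pd.DataFrame({
            "path": [f"mem://{s.seed_id}" for s in samples],
            "split": splits[:len(samples)],
            "class_label": [s.class_label for s in samples],
            "quality_label": [s.quality_label for s in samples],
            "seed_id": [s.seed_id for s in samples],
        })
        images = np.stack([s.image for s in samples]) if samples else np.zeros((0, 1, 1), np.float32)
        masks = np.stack([s.mask for s in samples]) if samples else None
        clean = np.stack([s.clean_image for s in samples]) if samples else None
        return cls(name=name, frame=frame, images=images, masks=masks, clean=clean)


def _decode_grayscale(path: Path) -> np.ndarray:
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    full_scale = 65535.0 if arr.dtype == np.uint16 or arr.max() > 255 else 255.0
    return (arr.astype(np.float32) / full_scale)


def load_dataset(manifest_path, root_dir=None, name: str | None = None) -> ModalitySource:
    """Load a manifest-bound image dataset into a :class:`ModalitySource`.

    Images decode to [0, 1]; masks binarize at half of full scale.  A missing
    file raises an error naming the offending record.
    """
    manifest_path = Path(manifest_path)
    root = Path(root_dir) if root_dir is not None else manifest_path.parent
    frame = pd.read_csv(manifest_path, keep_default_na=False)
    records = [ManifestRecord(**{k: (None if v == "" else v)
                                 for k, v in row.items() if k in ManifestRecord.__dataclass_fields__})
               for row in frame.to_dict("records")]
    images, masks, clean = [], [], []
    have_masks = have_clean = True
    for rec in records:
        img_path = root / rec.path
        if not img_path.exists():
            raise IOError(f"missing image {rec.path!r} referenced by the manifest")
        images.append(_decode_grayscale(img_path))
        if rec.mask_path:
            mask_path = root / rec.mask_path
            if not mask_path.exists():
                raise IOError(f"missing mask {rec.mask_path!r} referenced by the manifest")
            masks.append((_decode_grayscale(mask_path) >= 0.5).astype(np.uint8))
        else:
            have_masks = False
        if rec.clean_path:
            clean_path = root / rec.clean_path
            if not clean_path.exists():
                raise IOError(f"missing clean image {rec.clean_path!r} referenced by the manifest")
            clean.append(_decode_grayscale(clean_path))
        else:
            have_clean = False
    return ModalitySource(
        name=name or manifest_path.stem,
        frame=frame,
        images=np.stack(images) if images else np.zeros((0, 1, 1), np.float32),
        masks=np.stack(masks) if (have_masks and masks) else None,
        clean=np.stack(clean) if (have_clean and clean) else None,
    )
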