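"""Shared-representation backbones and their pretraining.

Two constructions are provided:

* :func:`build_cdae` — a convolutional denoising autoencoder: four encoder
  stages of strided 3x3 convolution + batch norm + ReLU (stride 2 replaces
  pooling), and a symmetric decoder of nearest-neighbour 2x upsampling +
  convolution + batch norm + ReLU stages, closed by a single-channel
  reconstruction convolution with a sigmoid.  Trained unsupervised on
  (noisy -> clean) pairs under MSE with RMSprop.
* :func:`build_supervised_backbone` — six stride-1 same-padded 3x3
  convolutions with ReLU, dilation 2 in the last three to widen the
  receptive field cheaply, followed by global average pooling, a hidden FC
  layer, dropout 0.5 and a softmax output.  Trained on class labels under
  categorical cross-entropy with Adam.

Both record an ``encoder_cut_point``: the deepest layer producing a spatial
feature map, where task heads attach.  Pretraining uses plateau-driven
learning-rate reduction and early stopping with best-weight restoration;
noise for the denoiser is re-sampled every epoch (a regularizer) unless
``fixed_noise`` asks for one deterministic corruption.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .arch import ArchitectureSpec, LayerSpec, batch_norm, build_network, conv2d, fc
from .image_io import MeanNormalizer, ModalitySource
from .metrics_losses import ms_ssim, psnr, ssim
from .phantom_data import NoiseSpec

DEFAULT_NOISE_LADDER = tuple([NoiseSpec("gaussian", s) for s in (10, 20, 30, 40, 50)]
                             + [NoiseSpec("poisson")])


@dataclass
class PretrainConfig:
    loss: str = "mse"                      # mse (denoising) or cce (supervised)
    optimizer: str = "rmsprop"
    batch_size: int = 16
    initial_lr: float = 1e-3
    plateau_factor: float = 0.5
    plateau_patience: int = 3
    early_stop_patience: int = 8
    max_epochs: int = 30
    seed: int = 0
    fixed_noise: bool = False

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if self.plateau_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patiences must be >= 1")


@dataclass
class BackboneModel:
    """A trained (or initialized) shared representation.

    ``net`` is the full pretraining network; ``encoder_cut_point`` indexes
    its deepest spatial-feature layer.  ``encoder()`` returns a view sharing
    the same layer objects, so heads attached to it alias theta_src.
    """

    arch: ArchitectureSpec
    net: nn.Sequential
    kind: str                              # "cdae" | "supervised"
    encoder_cut_point: int
    input_size: int
    widths: tuple[int, ...]
    normalizer: MeanNormalizer = field(default_factory=MeanNormalizer)
    classes: list[str] | None = None
    fc_width: int | None = None

    def encoder(self) -> nn.Sequential:
        return nn.Sequential(self.net.layers[:self.encoder_cut_point + 1])

    def decoder_layer_specs(self) -> list[LayerSpec]:
        return self.arch.layers[self.encoder_cut_point + 1:]

    def encoder_arch(self) -> ArchitectureSpec:
        return ArchitectureSpec(name=f"{self.arch.name}-encoder",
                                layers=self.arch.layers[:self.encoder_cut_point + 1],
                                input_shape=self.arch.input_shape)

    @property
    def encoder_channels(self) -> int:
        convs = [l for l in self.arch.layers[:self.encoder_cut_point + 1]
                 if l.kind == "conv2d"]
        return convs[-1].channels_out

    def theta_src(self) -> list[np.ndarray]:
        return self.encoder().get_state()

    def prepare(self, images: np.ndarray) -> np.ndarray:
        """Normalize a (N, H, W) stack into network input layout (N, 1, H, W)."""
        x = self.normalizer.transform(images.astype(np.float32))
        return x[:, None, :, :]


def build_cdae(widths: tuple[int, ...] = (16, 32, 64, 128), input_size: int = 64,
               seed: int = 0) -> BackboneModel:
    """Denoising-autoencoder backbone; ``input_size`` must be divisible by 16."""
    if len(widths) != 4:
        raise ValueError("cdae takes exactly four encoder widths")
    if input_size % 16 != 0:
        raise ValueError("input_size must be divisible by 16 (four stride-2 stages)")
    layers: list[LayerSpec] = []
    c = 1
    for w in widths:
        layers += [conv2d(c, w, kernel=3, stride=2), batch_norm(w), LayerSpec("relu")]
        c = w
    cut = len(layers) - 1
    dec_widths = list(widths[-2::-1]) + [widths[0]]   # e.g. (64, 32, 16, 16)
    for w in dec_widths:
        layers += [LayerSpec("upsample2x"), conv2d(c, w, kernel=3, stride=1),
                   batch_norm(w), LayerSpec("relu")]
        c = w
    layers += [conv2d(c, 1, kernel=3, stride=1), LayerSpec("sigmoid")]
    arch = ArchitectureSpec(name=f"cdae{input_size}-" + "x".join(map(str, widths)),
                            layers=layers, input_shape=(input_size, input_size, 1))
    net = build_network(arch, np.random.default_rng(seed))
    return BackboneModel(arch=arch, net=net, kind="cdae", encoder_cut_point=cut,
                         input_size=input_size, widths=tuple(widths))


def build_supervised_backbone(widths: tuple[int, ...] = (16, 32, 64, 64, 128, 128),
                              n_classes: int = 3, input_size: int = 64,
                              fc_width: int = 64, seed: int = 0) -> BackboneModel:
    """Supervised dilated-convolution backbone ending in GAP/FC/dropout/softmax."""
    if len(widths) != 6:
        raise ValueError("the supervised backbone takes exactly six conv widths")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    layers: list[LayerSpec] = []
    c = 1
    for i, w in enumerate(widths):
        dilation = 2 if i >= 3 else 1
        layers += [conv2d(c, w, kernel=3, stride=1, dilation=dilation),
                   LayerSpec("relu")]
        c = w
    cut = len(layers) - 1
    layers += [LayerSpec("gap"), fc(c, fc_width),
               LayerSpec("dropout", rate=0.5), fc(fc_width, n_classes),
               LayerSpec("softmax")]
    arch = ArchitectureSpec(name=f"sup{input_size}-" + "x".join(map(str, widths)),
                            layers=layers, input_shape=(input_size, input_size, 1))
    net = build_network(arch, np.random.default_rng(seed))
    return BackboneModel(arch=arch, net=net, kind="supervised", encoder_cut_point=cut,
                         input_size=input_size, widths=tuple(widths), fc_width=fc_width)


# ---------------------------------------------------------------------------
# Training loops
# ---------------------------------------------------------------------------

def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _noisy_batch(clean: np.ndarray, spec: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    """Vectorized counterpart of phantom_data.add_noise for (N, H, W) stacks."""
    scaled = clean.astype(np.float64) * 255.0
    if spec.kind == "gaussian":
        noisy = scaled + rng.normal(0.0, spec.sigma, clean.shape)
    elif spec.kind == "poisson":
        noisy = rng.poisson(scaled).astype(np.float64)
    else:
        noisy = scaled
    return (np.clip(noisy, 0.0, 255.0) / 255.0).astype(np.float32)


def _noisy_per_image(clean: np.ndarray, specs, rng) -> np.ndarray:
    """Round-robin one NoiseSpec per image across a stack."""
    out = np.empty_like(clean)
    for i in range(clean.shape[0]):
        out[i] = _noisy_batch(clean[i:i + 1], specs[i % len(specs)], rng)[0]
    return out


@dataclass
class _EarlyStopper:
    plateau_factor: float
    plateau_patience: int
    early_stop_patience: int
    best: float = float("inf")
    bad_epochs: int = 0
    best_state: list | None = None

    def update(self, val_loss: float, net: nn.Sequential, opt: nn.Optimizer) -> bool:
        """Record an epoch; returns True when training should stop."""
        if val_loss < self.best - 1e-9:
            self.best = val_loss
            self.bad_epochs = 0
            self.best_state = net.get_state()
            return False
        self.bad_epochs += 1
        if self.bad_epochs % self.plateau_patience == 0:
            opt.lr *= self.plateau_factor
        return self.bad_epochs >= self.early_stop_patience

    def restore(self, net: nn.Sequential) -> None:
        if self.best_state is not None:
            net.load_state(self.best_state)


def onehot(labels: np.ndarray, classes: list[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    out = np.zeros((len(labels), len(classes)), dtype=np.float32)
    for i, lab in enumerate(labels):
        out[i, index[lab]] = 1.0
    return out


def pretrain_denoising(model: BackboneModel, source: ModalitySource,
                       noise_specs=DEFAULT_NOISE_LADDER,
                       cfg: PretrainConfig | None = None,
                       ) -> tuple[BackboneModel, pd.DataFrame]:
    """Train the CDAE on (noisy -> clean) pairs; returns (model, history).

    Corruption is regenerated from a per-epoch seed (unless
    ``cfg.fixed_noise``), the validation corruption is fixed once, the
    learning rate halves (by ``plateau_factor``) when the validation MSE
    plateaus, and the best-validation weights are restored at the end.
    """
    cfg = cfg or PretrainConfig()
    noise_specs = list(noise_specs)
    train_clean = source.clean_for("train")
    if train_clean.shape[0] == 0:
        raise ValueError("empty train split")
    if model.normalizer.mean_ is None and not model.normalizer.per_image:
        model.normalizer.fit(train_clean)
    val_clean = source.clean_for("val")
    val_rng = np.random.default_rng([cfg.seed, 0xBEEF])
    val_noisy = _noisy_per_image(val_clean, noise_specs, val_rng) if val_clean.size else val_clean

    opt = nn.make_optimizer(cfg.optimizer, lr=cfg.initial_lr)
    stopper = _EarlyStopper(cfg.plateau_factor, cfg.plateau_patience, cfg.early_stop_patience)
    rows = []
    for epoch in range(cfg.max_epochs):
        noise_epoch = 0 if cfg.fixed_noise else epoch
        erng = np.random.default_rng([cfg.seed, 2, noise_epoch])
        brng = np.random.default_rng([cfg.seed, 3, epoch])
        noisy = _noisy_per_image(train_clean, noise_specs, erng)
        losses = []
        for idx in _batches(train_clean.shape[0], cfg.batch_size, brng):
            x = model.prepare(noisy[idx])
            t = train_clean[idx][:, None]
            y = model.net.forward(x, training=True)
            loss, g = nn.mse_vg(y, t)
            model.net.backward(g)
            opt.step(model.net.parameters(), model.net.gradients())
            losses.append(loss)
        val_loss = _denoising_val_loss(model, val_noisy, val_clean, cfg.batch_size)
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_loss": val_loss, "lr": opt.lr})
        if stopper.update(val_loss, model.net, opt):
            break
    stopper.restore(model.net)
    return model, pd.DataFrame(rows)


def _denoising_val_loss(model, val_noisy, val_clean, batch_size) -> float:
    if val_clean.shape[0] == 0:
        return float("nan")
    total, count = 0.0, 0
    for start in range(0, val_clean.shape[0], batch_size):
        x = model.prepare(val_noisy[start:start + batch_size])
        t = val_clean[start:start + batch_size][:, None]
        y = model.net.forward(x, training=False)
        total += float(np.sum((y - t) ** 2))
        count += t.size
    return total / count


def pretrain_supervised(model: BackboneModel, source: ModalitySource,
                        cfg: PretrainConfig | None = None,
                        label_column: str = "class_label",
                        ) -> tuple[BackboneModel, pd.DataFrame]:
    """Train the supervised backbone on class labels under CCE."""
    cfg = cfg or PretrainConfig(loss="cce", optimizer="adam")
    train_x = source.images_for("train")
    if train_x.shape[0] == 0:
        raise ValueError("empty train split")
    if model.normalizer.mean_ is None and not model.normalizer.per_image:
        model.normalizer.fit(train_x)
    classes = sorted(set(source.labels_for("train", label_column)))
    model.classes = classes
    t_train = onehot(source.labels_for("train", label_column), classes)
    val_x = source.images_for("val")
    t_val = onehot(source.labels_for("val", label_column), classes)

    opt = nn.make_optimizer(cfg.optimizer, lr=cfg.initial_lr)
    stopper = _EarlyStopper(cfg.plateau_factor, cfg.plateau_patience, cfg.early_stop_patience)
    rows = []
    for epoch in range(cfg.max_epochs):
        brng = np.random.default_rng([cfg.seed, 3, epoch])
        losses = []
        for idx in _batches(train_x.shape[0], cfg.batch_size, brng):
            x = model.prepare(train_x[idx])
            y = model.net.forward(x, training=True)
            loss, g = nn.cce_vg(y, t_train[idx])
            model.net.backward(g)
            opt.step(model.net.parameters(), model.net.gradients())
            losses.append(loss)
        val_loss, val_acc = _supervised_val(model, val_x, t_val, cfg.batch_size)
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_loss": val_loss, "val_accuracy": val_acc, "lr": opt.lr})
        if stopper.update(val_loss, model.net, opt):
            break
    stopper.restore(model.net)
    return model, pd.DataFrame(rows)


def _supervised_val(model, val_x, t_val, batch_size):
    if val_x.shape[0] == 0:
        return float("nan"), float("nan")
    losses, correct = [], 0
    for start in range(0, val_x.shape[0], batch_size):
        x = model.prepare(val_x[start:start + batch_size])
        t = t_val[start:start + batch_size]
        y = model.net.forward(x, training=False)
        loss, _ = nn.cce_vg(y, t)
        losses.append(loss * len(t))
        correct += int((y.argmax(axis=1) == t.argmax(axis=1)).sum())
    return float(np.sum(losses) / val_x.shape[0]), correct / val_x.shape[0]


def classify(model: BackboneModel, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Class probabilities from a trained supervised backbone (inference mode)."""
    out = []
    for start in range(0, images.shape[0], batch_size):
        x = model.prepare(images[start:start + batch_size])
        out.append(model.net.forward(x, training=False))
    return np.concatenate(out, axis=0)


def denoise(model: BackboneModel, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Reconstruct a (N, H, W) stack through a trained CDAE (inference mode)."""
    out = []
    for start in range(0, images.shape[0], batch_size):
        x = model.prepare(images[start:start + batch_size])
        out.append(model.net.forward(x, training=False)[:, 0])
    return np.concatenate(out, axis=0)


def evaluate_denoising(model: BackboneModel, source: ModalitySource,
                       noise_specs=DEFAULT_NOISE_LADDER, seed: int = 0,
                       include_noisy_input: bool = False) -> pd.DataFrame:
    """PSNR/SSIM/MS-SSIM of CDAE reconstructions per noise level on the test split.

    MS-SSIM uses as many dyadic scales (at most five) as the image size
    admits.  With ``include_noisy_input`` the metrics of the raw corrupted
    input are reported alongside.
    """
    clean = source.clean_for("test")
    size = clean.shape[1]
    n_scales = 1
    while n_scales < 5 and size // (2 ** n_scales) >= 11:
        n_scales += 1
    rows = []
    for k, spec in enumerate(noise_specs):
        rng = np.random.default_rng([seed, 4, k])
        noisy = _noisy_batch(clean, spec, rng)
        den = denoise(model, noisy)
        label = spec.kind if spec.kind != "gaussian" else f"gaussian(sigma={spec.sigma:g})"
        row = {"noise": label,
               "psnr": float(np.mean([psnr(c, d) for c, d in zip(clean, den)])),
               "ssim": float(np.mean([ssim(c, d) for c, d in zip(clean, den)])),
               "ms_ssim": float(np.mean([ms_ssim(c, d, n_scales=n_scales)
                                         for c, d in zip(clean, den)]))}
        if include_noisy_input:
            row["psnr_noisy"] = float(np.mean([psnr(c, nz) for c, nz in zip(clean, noisy)]))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_backbone(model: BackboneModel, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model.arch.to_yaml(out / "arch.yaml")
    arrays = {name: p for name, p in model.net.named_parameters()}
    for i, layer in enumerate(model.net.layers):
        if isinstance(layer, nn.BatchNorm):   # running stats are state, not params
            arrays[f"layer{i}.running_mean"] = layer.running_mean
            arrays[f"layer{i}.running_var"] = layer.running_var
    np.savez(out / "params.npz", **arrays)
    meta = {"kind": model.kind, "encoder_cut_point": model.encoder_cut_point,
            "input_size": model.input_size, "widths": list(model.widths),
            "normalizer": model.normalizer.to_dict(), "classes": model.classes,
            "fc_width": model.fc_width}
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    return out


def load_backbone(in_dir) -> BackboneModel:
    src = Path(in_dir)
    arch = ArchitectureSpec.from_yaml(src / "arch.yaml")
    meta = json.loads((src / "meta.json").read_text())
    net = build_network(arch, np.random.default_rng(0))
    with np.load(src / "params.npz") as data:
        state = [data[name] for name, _ in net.named_parameters()]
        net.load_state(state)
        for i, layer in enumerate(net.layers):
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean = data[f"layer{i}.running_mean"]
                layer.running_var = data[f"layer{i}.running_var"]
    return BackboneModel(arch=arch, net=net, kind=meta["kind"],
                         encoder_cut_point=meta["encoder_cut_point"],
                         input_size=meta["input_size"], widths=tuple(meta["widths"]),
                         normalizer=MeanNormalizer.from_dict(meta["normalizer"]),
                         classes=meta["classes"], fc_width=meta["fc_width"])
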