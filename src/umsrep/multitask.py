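"""Task heads on a shared backbone and the three fine-tuning strategies.

All heads attach at the backbone's ``encoder_cut_point`` and *alias* the
encoder parameters (theta_src): there is exactly one copy of the shared
state, referenced by every head.  Fine-tuning supports:

* ``independent`` — theta_src frozen (the encoder even runs in inference
  mode, so batch-norm running statistics cannot drift); each head minimizes
  its own loss with its own optimizer on its own data.
* ``alternating`` — tasks take turns in declaration order, task *i*
  receiving ``n_i`` consecutive batches per cycle; every batch updates
  theta_src and that task's head, with per-task optimizer state.
* ``joint`` — every step draws one batch per task, forms
  ``L = sum_i w_i L_i``, and applies a single Adam step to theta_src and
  all heads; the theta_src gradient is exactly the weighted sum of the
  per-task gradients.

Batch sampling reshuffles each task's training set with a per-(task, epoch)
seed, so identical configurations reproduce identical trajectories.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .arch import ArchitectureSpec, LayerSpec, build_network, conv2d, fc
from .backbone import BackboneModel, onehot
from .nn.losses import cce_vg, combined_seg_vg


class FinetuneError(ValueError):
    pass


@dataclass
class TaskSpec:
    name: str
    kind: str                               # "segmentation" | "classification"
    label_space: list[str] = field(default_factory=lambda: ["mask"])
    loss: str | None = None                 # defaults by kind
    optimizer: str = "adam"
    optimizer_kwargs: dict = field(default_factory=lambda: {"lr": 1e-3})
    fc_width: int = 64                      # classification heads only

    def __post_init__(self):
        if self.kind not in ("segmentation", "classification"):
            raise FinetuneError(f"unknown task kind {self.kind!r}")
        if self.loss is None:
            self.loss = "combined_seg" if self.kind == "segmentation" else "cce"
        if self.kind == "segmentation" and self.loss != "combined_seg":
            raise FinetuneError("segmentation tasks use the combined BCE+Dice loss")
        if self.kind == "classification" and len(self.label_space) < 2:
            raise FinetuneError("classification tasks need >= 2 labels")


@dataclass
class TaskData:
    """Training (and optional validation) arrays for one task."""
    images: np.ndarray                      # (N, H, W)
    targets: np.ndarray                     # masks (N, H, W) or label strings (N,)
    val_images: np.ndarray | None = None
    val_targets: np.ndarray | None = None


@dataclass
class TaskHead:
    task: TaskSpec
    arch: ArchitectureSpec
    net: nn.Sequential


@dataclass
class MultiTaskModel:
    backbone: BackboneModel
    heads: dict[str, TaskHead] = field(default_factory=dict)

    def encoder(self) -> nn.Sequential:
        return self.backbone.encoder()

    def head(self, task_name: str) -> TaskHead:
        try:
            return self.heads[task_name]
        except KeyError:
            raise FinetuneError(f"unknown task {task_name!r}; "
                                f"attached: {sorted(self.heads)}") from None

    def forward(self, task_name: str, images: np.ndarray, training: bool = False,
                ) -> np.ndarray:
        x = self.backbone.prepare(images)
        f = self.encoder().forward(x, training=training)
        return self.head(task_name).net.forward(f, training=training)


@dataclass
class Prediction:
    task: str
    kind: str
    label: str | None = None
    probabilities: np.ndarray | None = None
    mask: np.ndarray | None = None
    probability_map: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Head attachment
# ---------------------------------------------------------------------------

def attach_segmentation_head(model: MultiTaskModel, task: TaskSpec,
                             seed: int = 0) -> TaskHead:
    """Append a per-pixel sigmoid head producing masks at input resolution.

    On a CDAE backbone the pretrained decoder is reused: its stages are
    copied into the head (theta_task starts from the pretrained values) and
    the final reconstruction convolution is replaced by a freshly
    initialized single-channel convolution.  On a supervised (stride-1)
    backbone a new symmetric stack of stride-1 convolutions mirrors the
    encoder widths back down to one channel; no upsampling is needed since
    the encoder never downsamples.
    """
    if task.kind != "segmentation":
        raise FinetuneError("attach_segmentation_head needs a segmentation TaskSpec")
    bb = model.backbone
    rng = np.random.default_rng([seed, 11])
    if bb.kind == "cdae":
        specs = [copy.deepcopy(s) for s in bb.decoder_layer_specs()]
        arch = ArchitectureSpec(name=f"{task.name}-head", layers=specs,
                                input_shape=(bb.input_size // 16, bb.input_size // 16,
                                             bb.encoder_channels))
        net = build_network(arch, rng)
        # copy pretrained decoder weights for all stages before the final conv
        src_layers = bb.net.layers[bb.encoder_cut_point + 1:]
        for i, (spec, src) in enumerate(zip(specs, src_layers)):
            if i >= len(specs) - 2:   # final conv + sigmoid stay freshly initialized
                break
            for k, v in src.params.items():
                net.layers[i].params[k][...] = v
    else:
        widths = list(bb.widths[-2::-1]) + [bb.widths[0]]
        specs: list[LayerSpec] = []
        c = bb.encoder_channels
        for w in widths:
            specs += [conv2d(c, w, kernel=3, stride=1), LayerSpec("relu")]
            c = w
        specs += [conv2d(c, 1, kernel=3, stride=1), LayerSpec("sigmoid")]
        arch = ArchitectureSpec(name=f"{task.name}-head", layers=specs,
                                input_shape=(bb.input_size, bb.input_size,
                                             bb.encoder_channels))
        net = build_network(arch, rng)
    head = TaskHead(task=task, arch=arch, net=net)
    model.heads[task.name] = head
    return head


def attach_classification_head(model: MultiTaskModel, task: TaskSpec,
                               seed: int = 0) -> TaskHead:
    """Append a GAP -> FC -> dropout -> FC -> softmax head on the feature map."""
    if task.kind != "classification":
        raise FinetuneError("attach_classification_head needs a classification TaskSpec")
    bb = model.backbone
    c = bb.encoder_channels
    n_classes = len(task.label_space)
    specs = [LayerSpec("gap"), fc(c, task.fc_width), LayerSpec("dropout", rate=0.5),
             fc(task.fc_width, n_classes), LayerSpec("softmax")]
    feat = bb.input_size if bb.kind == "supervised" else bb.input_size // 16
    arch = ArchitectureSpec(name=f"{task.name}-head", layers=specs,
                            input_shape=(feat, feat, c))
    net = build_network(arch, np.random.default_rng([seed, 13]))
    head = TaskHead(task=task, arch=arch, net=net)
    model.heads[task.name] = head
    return head


# ---------------------------------------------------------------------------
# Fine-tuning
# ---------------------------------------------------------------------------

@dataclass
class FinetuneConfig:
    strategy: str = "independent"
    task_weights: dict[str, float] | None = None     # joint
    batch_ratios: dict[str, int] | None = None       # alternating
    epochs: int = 5
    batch_size: int = 16
    seed: int = 0
    joint_lr: float = 1e-3
    cycles: int | None = None                        # alternating; derived if None

    def __post_init__(self):
        if self.strategy not in ("independent", "alternating", "joint"):
            raise FinetuneError(f"unknown strategy {self.strategy!r}")
        if self.batch_size < 1 or self.epochs < 0:
            raise FinetuneError("batch_size >= 1 and epochs >= 0 required")


def alternating_schedule(batch_ratios: dict[str, int] | list[tuple[str, int]],
                         total_switch_cycles: int) -> list[str]:
    """Task order for alternating fine-tuning.

    Cycles through tasks in declaration order, emitting ``n_i`` consecutive
    batch slots for task *i* per cycle; the result has length
    ``cycles * sum(n_i)``.
    """
    items = list(batch_ratios.items()) if isinstance(batch_ratios, dict) else list(batch_ratios)
    if not items:
        raise FinetuneError("at least one task required")
    for name, r in items:
        if not isinstance(r, (int, np.integer)) or r < 1:
            raise FinetuneError(f"batch ratio for {name!r} must be a positive integer")
    schedule = []
    for _ in range(total_switch_cycles):
        for name, r in items:
            schedule.extend([name] * int(r))
    return schedule


class _BatchStream:
    """Per-task batch index stream with per-epoch reshuffling.

    Seeding depends only on (run seed, task index, epoch), so independent,
    alternating and joint runs that draw the same number of batches see the
    same batch sequence.
    """

    def __init__(self, n: int, batch_size: int, seed: int, task_index: int):
        self.n, self.batch_size = n, batch_size
        self.seed, self.task_index = seed, task_index
        self.epoch = -1
        self._queue: list[np.ndarray] = []

    def next(self) -> np.ndarray:
        if not self._queue:
            self.epoch += 1
            rng = np.random.default_rng([self.seed, 5, self.task_index, self.epoch])
            order = rng.permutation(self.n)
            self._queue = [order[i:i + self.batch_size]
                           for i in range(0, self.n, self.batch_size)]
        return self._queue.pop(0)

    @property
    def batches_per_epoch(self) -> int:
        return -(-self.n // self.batch_size)


def _prepare_targets(task: TaskSpec, targets: np.ndarray) -> np.ndarray:
    if task.kind == "classification":
        return onehot(np.asarray(targets), task.label_space)
    return np.asarray(targets, dtype=np.float32)[:, None]  # (N, 1, H, W)


def _loss_vg(task: TaskSpec, y: np.ndarray, t: np.ndarray):
    if task.loss == "cce":
        return cce_vg(y, t)
    return combined_seg_vg(y, t)


def _task_grad(model: MultiTaskModel, encoder: nn.Sequential, task_name: str,
               x_batch: np.ndarray, t_batch: np.ndarray, training: bool = True,
               freeze_src: bool = False):
    """One forward/backward for one task; returns (loss, enc_grads, head_grads).

    With ``freeze_src`` the encoder runs in inference mode and no encoder
    gradient is computed.
    """
    head = model.head(task_name)
    f = encoder.forward(x_batch, training=training and not freeze_src)
    y = head.net.forward(f, training=training)
    loss, g = _loss_vg(head.task, y, t_batch)
    gf = head.net.backward(g)
    head_grads = head.net.gradients()
    if freeze_src:
        return loss, None, head_grads
    encoder.backward(gf)
    return loss, encoder.gradients(), head_grads


def finetune(model: MultiTaskModel, cfg: FinetuneConfig,
             data: dict[str, TaskData]) -> dict[str, pd.DataFrame]:
    """Fine-tune all attached heads under the configured strategy.

    Returns per-task histories of (step, loss); joint additionally records
    the composite loss under the pseudo-task ``"__joint__"``.
    """
    missing = set(model.heads) - set(data)
    if missing:
        raise FinetuneError(f"no data supplied for tasks {sorted(missing)}")
    names = list(model.heads)
    encoder = model.encoder()
    prepared = {n: (model.backbone.prepare(data[n].images),
                    _prepare_targets(model.heads[n].task, data[n].targets))
                for n in names}
    streams = {n: _BatchStream(prepared[n][0].shape[0], cfg.batch_size, cfg.seed, i)
               for i, n in enumerate(names)}
    history: dict[str, list] = {n: [] for n in names}

    if cfg.strategy == "independent":
        for n in names:
            head = model.head(n)
            opt = nn.make_optimizer(head.task.optimizer, **head.task.optimizer_kwargs)
            stream = streams[n]
            for _ in range(cfg.epochs * stream.batches_per_epoch):
                idx = stream.next()
                x, t = prepared[n][0][idx], prepared[n][1][idx]
                loss, _, head_grads = _task_grad(model, encoder, n, x, t,
                                                 freeze_src=True)
                opt.step(head.net.parameters(), head_grads)
                history[n].append({"step": len(history[n]), "loss": loss})

    elif cfg.strategy == "alternating":
        ratios = cfg.batch_ratios or {n: 1 for n in names}
        if set(ratios) != set(names):
            raise FinetuneError("batch_ratios must cover exactly the attached tasks")
        cycles = cfg.cycles
        if cycles is None:
            per_cycle = {n: ratios[n] for n in names}
            cycles = max(1, cfg.epochs * max(
                -(-streams[n].batches_per_epoch // per_cycle[n]) for n in names))
        schedule = alternating_schedule({n: ratios[n] for n in names}, cycles)
        opts = {n: nn.make_optimizer(model.head(n).task.optimizer,
                                     **model.head(n).task.optimizer_kwargs)
                for n in names}
        for n in schedule:
            idx = streams[n].next()
            x, t = prepared[n][0][idx], prepared[n][1][idx]
            loss, enc_grads, head_grads = _task_grad(model, encoder, n, x, t)
            head = model.head(n)
            opts[n].step(encoder.parameters() + head.net.parameters(),
                         enc_grads + head_grads)
            history[n].append({"step": len(history[n]), "loss": loss})

    else:  # joint
        weights = cfg.task_weights or {n: 1.0 for n in names}
        if set(weights) != set(names):
            raise FinetuneError("task_weights must cover exactly the attached tasks")
        if any(w < 0 for w in weights.values()) or not any(weights.values()):
            raise FinetuneError("weights must be >= 0 and not all zero")
        opt = nn.Adam(lr=cfg.joint_lr)
        steps = cfg.epochs * max(streams[n].batches_per_epoch for n in names)
        history["__joint__"] = []
        for step in range(steps):
            enc_acc = [np.zeros_like(p) for p in encoder.parameters()]
            head_grad_bag = []
            composite = 0.0
            for n in names:
                idx = streams[n].next()
                x, t = prepared[n][0][idx], prepared[n][1][idx]
                loss, enc_grads, head_grads = _task_grad(model, encoder, n, x, t)
                w = weights[n]
                for acc, g in zip(enc_acc, enc_grads):
                    acc += w * g
                head_grad_bag.extend(w * g for g in head_grads)
                composite += w * loss
                history[n].append({"step": step, "loss": loss})
            all_params = encoder.parameters() + [p for n in names
                                                 for p in model.head(n).net.parameters()]
            opt.step(all_params, enc_acc + head_grad_bag)
            history["__joint__"].append({"step": step, "loss": composite})

    return {k: pd.DataFrame(v) for k, v in history.items()}


def joint_theta_src_gradient(model: MultiTaskModel, batches: dict[str, tuple],
                             weights: dict[str, float]) -> list[np.ndarray]:
    """Weighted-sum theta_src gradient for fixed batches at the current point.

    ``batches`` maps task name to ``(prepared_inputs, prepared_targets)``.
    Dropout layers should be disabled (rate 0) for a deterministic value.
    """
    encoder = model.encoder()
    acc = [np.zeros_like(p, dtype=np.float64) for p in encoder.parameters()]
    for n, (x, t) in batches.items():
        _, enc_grads, _ = _task_grad(model, encoder, n, x, t)
        for a, g in zip(acc, enc_grads):
            a += weights[n] * g
    return acc


def predict(model: MultiTaskModel, task_name: str, image: np.ndarray,
            threshold: float = 0.5) -> Prediction:
    """Inference for one image; dropout disabled, batch norm in running mode.

    Segmentation thresholds the probability map at 0.5 with ties mapping to
    foreground; classification returns the argmax label and the probability
    vector.
    """
    head = model.head(task_name)
    y = model.forward(task_name, image[None], training=False)
    if head.task.kind == "segmentation":
        pmap = y[0, 0]
        return Prediction(task=task_name, kind="segmentation",
                          mask=(pmap >= threshold).astype(np.uint8),
                          probability_map=pmap)
    probs = y[0]
    return Prediction(task=task_name, kind="classification",
                      label=head.task.label_space[int(probs.argmax())],
                      probabilities=probs)
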