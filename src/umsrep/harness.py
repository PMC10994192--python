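"""Desk-scale reference experiments on phantom data.

These are the package's reproducible stand-ins for the full-scale studies:
each function generates seeded phantoms, trains the relevant model at a
size a laptop CPU handles in about a minute, and returns the measured
quantities.  Problem sizes and widths are deliberately small; the methods
note documents them.  Both the test suite and ``scripts/acceptance.py``
call these functions, so the numbers they report are always recomputed.
"""

from __future__ import annotations

import numpy as np

from .backbone import (PretrainConfig, build_cdae, build_supervised_backbone,
                       classify, denoise, pretrain_denoising, pretrain_supervised)
from .derivable import grad_cam
from .image_io import ModalitySource
from .metrics_losses import iou, psnr
from .multitask import (FinetuneConfig, MultiTaskModel, TaskData, TaskSpec,
                        attach_classification_head, attach_segmentation_head,
                        finetune)
from .phantom_data import NoiseSpec, PhantomConfig, generate_phantoms


def _source(config: PhantomConfig, name: str) -> ModalitySource:
    return ModalitySource.from_samples(generate_phantoms(config), name=name)


# ---------------------------------------------------------------------------
# Denoising backbone
# ---------------------------------------------------------------------------

def denoising_experiment(seed: int = 0, n_samples: int = 2000, image_size: int = 64,
                         sigma: float = 30.0, widths=(16, 32, 64, 128),
                         max_epochs: int = 5) -> dict:
    """Train the CDAE on noisy X-ray-like phantoms and measure reconstruction.

    Returns test-split PSNR of the denoised output vs the raw noisy input at
    the training noise level, plus the raw-input PSNR ladder across the
    sigma = 10..50 Gaussian levels (which must decrease monotonically).
    """
    cfg = PhantomConfig(image_size=image_size, style="xray_like",
                        n_samples=n_samples, abnormal_fraction=0.5, seed=seed)
    source = _source(cfg, "cxr-phantom")
    model = build_cdae(widths=widths, input_size=image_size, seed=seed)
    pre = PretrainConfig(loss="mse", optimizer="rmsprop", batch_size=16,
                         initial_lr=1e-3, max_epochs=max_epochs, seed=seed)
    model, history = pretrain_denoising(model, source,
                                        noise_specs=[NoiseSpec("gaussian", sigma)],
                                        cfg=pre)
    clean = source.clean_for("test")
    rng = np.random.default_rng([seed, 21])
    noisy = np.stack([_gauss(c, sigma, rng) for c in clean])
    den = denoise(model, noisy)
    psnr_noisy = float(np.mean([psnr(c, x) for c, x in zip(clean, noisy)]))
    psnr_denoised = float(np.mean([psnr(c, x) for c, x in zip(clean, den)]))

    ladder = {}
    for s in (10, 20, 30, 40, 50):
        lrng = np.random.default_rng([seed, 22, s])
        nz = np.stack([_gauss(c, s, lrng) for c in clean])
        ladder[s] = float(np.mean([psnr(c, x) for c, x in zip(clean, nz)]))

    return {"psnr_denoised": psnr_denoised, "psnr_noisy": psnr_noisy,
            "psnr_ladder": ladder, "history": history, "model": model,
            "source": source}


def _gauss(img: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    noisy = img.astype(np.float64) * 255.0 + rng.normal(0.0, sigma, img.shape)
    return (np.clip(noisy, 0, 255) / 255.0).astype(np.float32)


# ---------------------------------------------------------------------------
# Supervised backbone
# ---------------------------------------------------------------------------

def supervised_experiment(seed: int = 0, n_samples: int = 600, image_size: int = 64,
                          widths=(8, 16, 16, 16, 32, 32), fc_width: int = 32,
                          max_epochs: int = 8) -> dict:
    """Train the dilated supervised backbone on 3-class Doppler-like phantoms."""
    cfg = PhantomConfig(image_size=image_size, style="doppler_like",
                        n_samples=n_samples, seed=seed)
    source = _source(cfg, "echo-phantom")
    model = build_supervised_backbone(widths=widths, n_classes=3,
                                      input_size=image_size, fc_width=fc_width,
                                      seed=seed)
    pre = PretrainConfig(loss="cce", optimizer="adam", batch_size=16,
                         initial_lr=1e-3, max_epochs=max_epochs, seed=seed)
    model, history = pretrain_supervised(model, source, cfg=pre)
    probs = classify(model, source.images_for("test"))
    pred = np.array(model.classes)[probs.argmax(axis=1)]
    truth = source.labels_for("test")
    acc = float(np.mean(pred == truth))
    return {"test_accuracy": acc, "history": history, "model": model,
            "source": source}


# ---------------------------------------------------------------------------
# Grad-CAM localization
# ---------------------------------------------------------------------------

def gradcam_experiment(seed: int = 0, n_samples: int = 500, image_size: int = 64,
                       widths=(8, 8, 16, 16, 16, 16), fc_width: int = 32,
                       max_epochs: int = 8, n_eval: int = 50,
                       lesion_contrast: float = 0.6) -> dict:
    """Lesion localization: does the heatmap argmax land in the lesion box?

    A stride-1 dilated backbone is trained to separate normal from abnormal
    X-ray-like phantoms, its own classification layers are adopted as the
    task head, and gradient-CAM heatmaps are computed for ``n_eval`` freshly
    generated abnormal phantoms.  Reports the fraction whose heatmap argmax
    falls inside the lesion bounding box.
    """
    cfg = PhantomConfig(image_size=image_size, style="xray_like",
                        n_samples=n_samples, abnormal_fraction=0.5,
                        lesion_contrast=lesion_contrast, seed=seed)
    source = _source(cfg, "cxr-phantom")
    model = build_supervised_backbone(widths=widths, n_classes=2,
                                      input_size=image_size, fc_width=fc_width,
                                      seed=seed)
    pre = PretrainConfig(loss="cce", optimizer="adam", batch_size=16,
                         initial_lr=1e-3, max_epochs=max_epochs, seed=seed)
    model, history = pretrain_supervised(model, source, cfg=pre)

    mtm = MultiTaskModel(backbone=model)
    adopt_pretraining_head(mtm, TaskSpec(name="abnormality", kind="classification",
                                         label_space=model.classes))

    eval_cfg = PhantomConfig(image_size=image_size, style="xray_like",
                             n_samples=n_eval, class_mix={"normal": 0.0, "abnormal": 1.0},
                             lesion_contrast=lesion_contrast, seed=seed + 1)
    hits = 0
    for s in generate_phantoms(eval_cfg):
        amap = grad_cam(mtm, "abnormality", s.clean_image)
        r, c = np.unravel_index(int(amap.heatmap.argmax()), amap.heatmap.shape)
        r0, c0, r1, c1 = s.lesion_bbox
        hits += int(r0 <= r < r1 and c0 <= c < c1)
    return {"hit_rate": hits / n_eval, "n_eval": n_eval, "history": history,
            "model": mtm}


def adopt_pretraining_head(model: MultiTaskModel, task: TaskSpec) -> None:
    """Expose a supervised backbone's own classification layers as a task head.

    The head *aliases* the backbone's pretrained GAP/FC/dropout/FC/softmax
    layers rather than copying them.
    """
    from . import nn
    from .arch import ArchitectureSpec

    bb = model.backbone
    if bb.kind != "supervised":
        raise ValueError("only supervised backbones carry a pretraining head")
    specs = bb.arch.layers[bb.encoder_cut_point + 1:]
    arch = ArchitectureSpec(name=f"{task.name}-head", layers=specs,
                            input_shape=(bb.input_size, bb.input_size,
                                         bb.encoder_channels))
    net = nn.Sequential(bb.net.layers[bb.encoder_cut_point + 1:])
    from .multitask import TaskHead
    model.heads[task.name] = TaskHead(task=task, arch=arch, net=net)


# ---------------------------------------------------------------------------
# Strategy-ordering harnesses
# ---------------------------------------------------------------------------

DEFAULT_STRATEGY_SEEDS = (0, 1, 2, 3, 4)


def cooperative_strategy_experiment(seeds=DEFAULT_STRATEGY_SEEDS, n_samples: int = 360,
                                    image_size: int = 32, widths=(8, 8, 16, 16, 16, 16),
                                    fc_width: int = 24, pretrain_epochs: int = 4,
                                    finetune_epochs: int = 8) -> dict:
    """Joint vs independent fine-tuning on three cooperative flow tasks.

    Three binary flow-discrimination heads (TR/MV, TR/MA, MV/MA) share a
    briefly pretrained supervised backbone.  Independent fine-tuning freezes
    the backbone; joint fine-tuning (equal weights) can keep adapting it.
    Mean test accuracy over tasks is reported per seed.
    """
    pairs = [("TR", "MV"), ("TR", "MA"), ("MV", "MA")]
    per_seed = {"joint": [], "independent": []}
    for seed in seeds:
        cfg = PhantomConfig(image_size=image_size, style="doppler_like",
                            n_samples=n_samples, seed=seed)
        source = _source(cfg, "echo-phantom")
        bb0 = build_supervised_backbone(widths=widths, n_classes=3,
                                        input_size=image_size, fc_width=fc_width,
                                        seed=seed)
        pre = PretrainConfig(loss="cce", optimizer="adam", batch_size=16,
                             initial_lr=1e-3, max_epochs=pretrain_epochs, seed=seed)
        bb0, _ = pretrain_supervised(bb0, source, cfg=pre)
        state = bb0.net.get_state()

        task_data = {}
        tasks = []
        for a, b in pairs:
            name = f"{a}_vs_{b}"
            tasks.append(TaskSpec(name=name, kind="classification",
                                  label_space=[a, b], fc_width=fc_width))
            task_data[name] = _binary_subset(source, a, b)

        for strategy in ("independent", "joint"):
            bb0.net.load_state(state)
            mtm = MultiTaskModel(backbone=bb0)
            for t in tasks:
                attach_classification_head(mtm, t, seed=seed)
            fcfg = FinetuneConfig(strategy=strategy, epochs=finetune_epochs,
                                  batch_size=16, seed=seed,
                                  task_weights={t.name: 1.0 for t in tasks}
                                  if strategy == "joint" else None)
            finetune(mtm, fcfg, {k: v[0] for k, v in task_data.items()})
            accs = [_head_accuracy(mtm, t.name, *task_data[t.name][1])
                    for t in tasks]
            per_seed[strategy].append(float(np.mean(accs)))

    return {"seeds": list(seeds),
            "joint_per_seed": per_seed["joint"],
            "independent_per_seed": per_seed["independent"],
            "joint_mean": float(np.mean(per_seed["joint"])),
            "independent_mean": float(np.mean(per_seed["independent"]))}


def _binary_subset(source: ModalitySource, a: str, b: str):
    def pick(split):
        idx = source.indices(split)
        labels = source.frame.loc[idx, "class_label"].to_numpy()
        keep = np.isin(labels, [a, b])
        return source.images[idx[keep]], labels[keep]

    xtr, ytr = pick("train")
    xte, yte = pick("test")
    return TaskData(images=xtr, targets=ytr), (xte, yte)


def _head_accuracy(mtm: MultiTaskModel, task_name: str, images, labels) -> float:
    y = mtm.forward(task_name, images, training=False)
    space = mtm.head(task_name).task.label_space
    pred = np.array(space)[y.argmax(axis=1)]
    return float(np.mean(pred == labels))


def conflicting_strategy_experiment(seeds=DEFAULT_STRATEGY_SEEDS, n_samples: int = 240,
                                    image_size: int = 32, widths=(8, 8, 16, 16),
                                    pretrain_epochs: int = 2, finetune_epochs: int = 6,
                                    sigma: float = 20.0,
                                    conflict_weight: float = 4.0) -> dict:
    """Independent vs joint fine-tuning with a deliberately conflicting partner.

    The segmentation task (lung masks) is paired with a second segmentation
    head whose targets are the masks of *other* images (a fixed random
    permutation), so its dense per-pixel gradients carry no signal the
    encoder could satisfy — an adversarial stand-in for negative transfer
    between unrelated tasks.  Joint fine-tuning lets that gradient noise
    reach theta_src; independent fine-tuning shields it.  Mean test IoU of
    the true segmentation head is reported per seed.
    """
    per_seed = {"joint": [], "independent": []}
    for seed in seeds:
        cfg = PhantomConfig(image_size=image_size, style="xray_like",
                            n_samples=n_samples, abnormal_fraction=0.5, seed=seed)
        source = _source(cfg, "cxr-phantom")
        bb0 = build_cdae(widths=widths, input_size=image_size, seed=seed)
        pre = PretrainConfig(loss="mse", optimizer="rmsprop", batch_size=16,
                             initial_lr=1e-3, max_epochs=pretrain_epochs, seed=seed)
        bb0, _ = pretrain_denoising(bb0, source,
                                    noise_specs=[NoiseSpec("gaussian", sigma)],
                                    cfg=pre)
        state = bb0.net.get_state()

        seg = TaskSpec(name="lung_seg", kind="segmentation")
        conflict = TaskSpec(name="conflict", kind="classification",
                            label_space=["normal", "abnormal"], fc_width=16)
        rng = np.random.default_rng([seed, 31])
        xtr = source.images_for("train")
        seg_data = TaskData(images=xtr, targets=source.masks_for("train"))
        shuffled = source.labels_for("train")[rng.permutation(xtr.shape[0])]
        conflict_data = TaskData(images=xtr, targets=shuffled)
        xte, mte = source.images_for("test"), source.masks_for("test")

        for strategy in ("independent", "joint"):
            bb0.net.load_state(state)
            mtm = MultiTaskModel(backbone=bb0)
            attach_segmentation_head(mtm, seg, seed=seed)
            attach_classification_head(mtm, conflict, seed=seed)
            # the unlearnable task is weighted up so its gradient noise
            # dominates the joint objective: the worst case for sharing
            fcfg = FinetuneConfig(strategy=strategy, epochs=finetune_epochs,
                                  batch_size=16, seed=seed,
                                  task_weights={"lung_seg": 1.0, "conflict": conflict_weight}
                                  if strategy == "joint" else None)
            finetune(mtm, fcfg, {"lung_seg": seg_data, "conflict": conflict_data})
            y = mtm.forward("lung_seg", xte, training=False)[:, 0]
            ious = [iou(m, p >= 0.5) for m, p in zip(mte, y)]
            per_seed[strategy].append(float(np.mean(ious)))

    return {"seeds": list(seeds),
            "joint_per_seed": per_seed["joint"],
            "independent_per_seed": per_seed["independent"],
            "joint_mean": float(np.mean(per_seed["joint"])),
            "independent_mean": float(np.mean(per_seed["independent"]))}
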