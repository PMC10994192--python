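"""Config-driven end-to-end experiments on phantom data.

``run_experiment`` executes the full training sequence — generate phantoms,
pretrain the shared backbone, attach task heads, fine-tune under each
requested strategy, evaluate on one shared test split, run the derivable
tasks, and account for parameter budgets — and writes every artifact as
CSV/JSON under the report directory.  With ``baseline: true`` it also
trains one separate end-to-end model per task (plus a separate denoiser for
the CDAE path) so the proposed-vs-baseline comparison mirrors the reference
experiments.  Measured wall-clock times are reported but never asserted;
they are hardware facts, not contracts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arch import budget_report, count_parameters
from .backbone import (BackboneModel, PretrainConfig, build_cdae,
                       build_supervised_backbone, pretrain_denoising,
                       pretrain_supervised)
from .derivable import grad_cam
from .image_io import ModalitySource
from .metrics_losses import (classification_metrics, confusion_from_labels, iou,
                             mcnemar_test)
from .multitask import (FinetuneConfig, MultiTaskModel, TaskData, TaskSpec,
                        attach_classification_head, attach_segmentation_head,
                        finetune)
from .phantom_data import NoiseSpec, PhantomConfig, generate_phantoms

log = logging.getLogger("umsrep")


class StageError(RuntimeError):
    """Raised when an experiment stage fails; names the stage."""


@dataclass
class TaskConfig:
    name: str
    kind: str
    target: str = "mask"            # "mask" | "class_label" | "quality_label"
    label_space: list[str] | None = None
    optimizer: str = "adam"
    lr: float = 1e-3
    weight: float = 1.0
    ratio: int = 1
    fc_width: int = 32


@dataclass
class ExperimentConfig:
    data: PhantomConfig
    backbone_mode: str = "cdae"
    backbone_widths: tuple[int, ...] | None = None
    fc_width: int = 32
    pretrain: PretrainConfig = field(default_factory=PretrainConfig)
    noise_specs: list[NoiseSpec] = field(default_factory=lambda: [NoiseSpec("gaussian", 30)])
    tasks: list[TaskConfig] = field(default_factory=list)
    strategies: list[str] = field(default_factory=lambda: ["independent"])
    finetune_epochs: int = 4
    batch_size: int = 16
    baseline: bool = False
    out_dir: str = "umsrep-report"
    seeds: list[int] = field(default_factory=lambda: [0])
    gradcam_examples: int = 0

    def __post_init__(self):
        if not self.tasks:
            raise ValueError("at least one task is required")
        if not self.seeds:
            raise ValueError("seeds must be non-empty")
        if self.backbone_widths is None:
            self.backbone_widths = ((8, 8, 16, 16) if self.backbone_mode == "cdae"
                                    else (8, 8, 16, 16, 16, 16))

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        data = d.pop("data")
        noise = data.pop("noise", None)
        if noise is not None:
            data["noise"] = NoiseSpec(**noise)
        bb = d.pop("backbone", {})
        pre = bb.pop("pretrain", {})
        specs = [NoiseSpec(**n) for n in bb.pop("noise_specs", [])]
        tasks = [TaskConfig(**t) for t in d.pop("tasks")]
        report = d.pop("report", {})
        return cls(data=PhantomConfig(**data),
                   backbone_mode=bb.pop("mode", "cdae"),
                   backbone_widths=tuple(bb["widths"]) if "widths" in bb else None,
                   fc_width=bb.pop("fc_width", 32),
                   pretrain=PretrainConfig(**pre),
                   noise_specs=specs or [NoiseSpec("gaussian", 30)],
                   tasks=tasks,
                   out_dir=report.pop("out_dir", "umsrep-report"),
                   seeds=list(report.pop("seeds", [0])),
                   gradcam_examples=report.pop("gradcam_examples", 0),
                   **d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 — re-raise with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("pretrain")
def _build_and_pretrain(cfg: ExperimentConfig, source: ModalitySource,
                        seed: int) -> BackboneModel:
    pre = PretrainConfig(**{**cfg.pretrain.__dict__, "seed": seed})
    if cfg.backbone_mode == "cdae":
        bb = build_cdae(widths=cfg.backbone_widths,
                        input_size=cfg.data.image_size, seed=seed)
        bb, _ = pretrain_denoising(bb, source, noise_specs=cfg.noise_specs, cfg=pre)
    else:
        n_classes = len(set(source.frame["class_label"]))
        bb = build_supervised_backbone(widths=cfg.backbone_widths,
                                       n_classes=n_classes,
                                       input_size=cfg.data.image_size,
                                       fc_width=cfg.fc_width, seed=seed)
        pre.loss, pre.optimizer = "cce", "adam"
        bb, _ = pretrain_supervised(bb, source, cfg=pre)
    return bb


def _task_spec(tc: TaskConfig, source: ModalitySource) -> TaskSpec:
    if tc.kind == "classification":
        space = tc.label_space or sorted(set(source.frame[tc.target]))
        return TaskSpec(name=tc.name, kind="classification", label_space=space,
                        optimizer=tc.optimizer, optimizer_kwargs={"lr": tc.lr},
                        fc_width=tc.fc_width)
    return TaskSpec(name=tc.name, kind="segmentation", optimizer=tc.optimizer,
                    optimizer_kwargs={"lr": tc.lr})


def _task_data(tc: TaskConfig, source: ModalitySource) -> TaskData:
    x = source.images_for("train")
    if tc.kind == "segmentation":
        return TaskData(images=x, targets=source.masks_for("train"))
    labels = source.labels_for("train", tc.target)
    if tc.label_space:
        keep = np.isin(labels, tc.label_space)
        return TaskData(images=x[keep], targets=labels[keep])
    return TaskData(images=x, targets=labels)


@_stage("evaluate")
def _evaluate(mtm: MultiTaskModel, cfg: ExperimentConfig,
              source: ModalitySource) -> tuple[pd.DataFrame, dict]:
    """Shared-test-split metrics per task, plus correctness vectors for McNemar."""
    rows, correctness = [], {}
    for tc in cfg.tasks:
        xte = source.images_for("test")
        if tc.kind == "segmentation":
            mte = source.masks_for("test")
            y = mtm.forward(tc.name, xte, training=False)[:, 0]
            pred = (y >= 0.5)
            ious = [iou(m, p) for m, p in zip(mte, pred)]
            flat_t = mte.astype(bool).ravel()
            flat_p = pred.ravel()
            c = confusion_from_labels(flat_t, flat_p, True)
            m = classification_metrics(c)
            rows.append({"task": tc.name, "accuracy": m["accuracy"],
                         "f_score": m["f_score"], "iou": float(np.mean(ious)),
                         "mcc": float("nan")})
            correctness[tc.name] = np.array([v >= 0.5 for v in ious])
        else:
            labels = source.labels_for("test", tc.target)
            if tc.label_space:
                keep = np.isin(labels, tc.label_space)
                xs, labels = xte[keep], labels[keep]
            else:
                xs = xte
            space = mtm.head(tc.name).task.label_space
            y = mtm.forward(tc.name, xs, training=False)
            pred = np.array(space)[y.argmax(axis=1)]
            acc = float(np.mean(pred == labels))
            # one-vs-rest macro average for multi-class tasks
            per = [classification_metrics(confusion_from_labels(labels, pred, c))
                   for c in space]
            rows.append({"task": tc.name, "accuracy": acc,
                         "f_score": float(np.mean([p["f_score"] for p in per])),
                         "iou": float("nan"),
                         "mcc": float(np.mean([p["mcc"] for p in per]))})
            correctness[tc.name] = pred == labels
    return pd.DataFrame(rows), correctness


def _mcnemar_table(correct_by_strategy: dict[str, dict]) -> pd.DataFrame:
    rows = []
    for s1, s2 in combinations(correct_by_strategy, 2):
        for task in correct_by_strategy[s1]:
            a = correct_by_strategy[s1][task]
            b_vec = correct_by_strategy[s2][task]
            b = int(np.sum(a & ~b_vec))
            c = int(np.sum(~a & b_vec))
            rows.append({"task": task, "strategy_1": s1, "strategy_2": s2,
                         "b": b, "c": c, "p_value": mcnemar_test(b, c)})
    return pd.DataFrame(rows)


@_stage("budget")
def _budget(cfg: ExperimentConfig, mtm: MultiTaskModel,
            times: dict[str, float]) -> pd.DataFrame:
    components = {"shared backbone": count_parameters(mtm.backbone.arch)}
    proposed = ["shared backbone"]
    baseline = []
    for tc in cfg.tasks:
        head = mtm.head(tc.name)
        hname = f"{tc.name} head"
        components[hname] = count_parameters(head.arch)
        proposed.append(hname)
        sname = f"separate {tc.name} model"
        components[sname] = (count_parameters(mtm.backbone.encoder_arch())
                             + count_parameters(head.arch))
        baseline.append(sname)
    if cfg.backbone_mode == "cdae":
        components["separate denoising model"] = count_parameters(mtm.backbone.arch)
        baseline.insert(0, "separate denoising model")
    report = budget_report(components, proposed, baseline, times=times)
    frame = report.to_frame()
    frame.attrs["reduction_pct"] = report.reduction_pct
    return frame


def run_experiment(cfg: ExperimentConfig) -> Path:
    """Run the full proposed-vs-baseline experiment; returns the report dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {"seeds": cfg.seeds, "strategies": cfg.strategies}
    for seed in cfg.seeds:
        seed_dir = out / f"seed-{seed}"
        seed_dir.mkdir(exist_ok=True)
        log.info("seed %d: generating phantoms", seed)
        try:
            data_cfg = PhantomConfig(**{**cfg.data.__dict__, "seed": seed})
            source = ModalitySource.from_samples(generate_phantoms(data_cfg))
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage 'generate' failed: {exc}") from exc

        t0 = time.perf_counter()
        bb = _build_and_pretrain(cfg, source, seed)
        times = {"shared backbone": (time.perf_counter() - t0) / 60.0}
        state = bb.net.get_state()

        correct_by_strategy: dict[str, dict] = {}
        mtm = None
        for strategy in cfg.strategies:
            log.info("seed %d: fine-tuning (%s)", seed, strategy)
            bb.net.load_state(state)
            mtm = MultiTaskModel(backbone=bb)
            for tc in cfg.tasks:
                spec = _task_spec(tc, source)
                if tc.kind == "segmentation":
                    attach_segmentation_head(mtm, spec, seed=seed)
                else:
                    attach_classification_head(mtm, spec, seed=seed)
            data = {tc.name: _task_data(tc, source) for tc in cfg.tasks}
            fcfg = FinetuneConfig(
                strategy=strategy, epochs=cfg.finetune_epochs,
                batch_size=cfg.batch_size, seed=seed,
                task_weights={tc.name: tc.weight for tc in cfg.tasks}
                if strategy == "joint" else None,
                batch_ratios={tc.name: tc.ratio for tc in cfg.tasks}
                if strategy == "alternating" else None)
            t0 = time.perf_counter()
            try:
                finetune(mtm, fcfg, data)
            except Exception as exc:  # noqa: BLE001
                raise StageError(f"stage 'finetune:{strategy}' failed: {exc}") from exc
            for tc in cfg.tasks:
                times.setdefault(f"{tc.name} head", 0.0)
                times[f"{tc.name} head"] += (time.perf_counter() - t0) / 60.0 / len(cfg.tasks)
            metrics, correctness = _evaluate(mtm, cfg, source)
            metrics.insert(0, "strategy", strategy)
            metrics.to_csv(seed_dir / f"metrics_{strategy}.csv", index=False)
            correct_by_strategy[strategy] = correctness

        if cfg.baseline:
            base_rows = _run_baseline(cfg, source, seed, times)
            pd.DataFrame(base_rows).to_csv(seed_dir / "metrics_baseline.csv", index=False)

        if len(correct_by_strategy) > 1:
            _mcnemar_table(correct_by_strategy).to_csv(seed_dir / "mcnemar.csv", index=False)

        budget = _budget(cfg, mtm, times)
        budget.to_csv(seed_dir / "budget.csv", index=False)
        summary[f"seed-{seed}"] = {"reduction_pct": budget.attrs["reduction_pct"]}

        if cfg.gradcam_examples:
            _write_heatmaps(cfg, mtm, source, seed_dir)

    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return out


def _run_baseline(cfg: ExperimentConfig, source: ModalitySource, seed: int,
                  times: dict[str, float]) -> list[dict]:
    """Separate end-to-end model (fresh backbone + head) per task."""
    rows = []
    for tc in cfg.tasks:
        t0 = time.perf_counter()
        if cfg.backbone_mode == "cdae":
            bb = build_cdae(widths=cfg.backbone_widths,
                            input_size=cfg.data.image_size, seed=seed + 100)
        else:
            n_classes = len(set(source.frame["class_label"]))
            bb = build_supervised_backbone(widths=cfg.backbone_widths,
                                           n_classes=n_classes,
                                           input_size=cfg.data.image_size,
                                           fc_width=cfg.fc_width, seed=seed + 100)
        bb.normalizer.fit(source.images_for("train"))
        mtm = MultiTaskModel(backbone=bb)
        spec = _task_spec(tc, source)
        if tc.kind == "segmentation":
            attach_segmentation_head(mtm, spec, seed=seed + 100)
        else:
            attach_classification_head(mtm, spec, seed=seed + 100)
        # end-to-end from random initialization: backbone and head both train
        fcfg = FinetuneConfig(strategy="alternating", epochs=cfg.finetune_epochs,
                              batch_size=cfg.batch_size, seed=seed,
                              batch_ratios={tc.name: 1})
        finetune(mtm, fcfg, {tc.name: _task_data(tc, source)})
        sub = ExperimentConfig(**{**cfg.__dict__, "tasks": [tc]})
        metrics, _ = _evaluate(mtm, sub, source)
        metrics.insert(0, "strategy", "baseline")
        rows.extend(metrics.to_dict("records"))
        times[f"separate {tc.name} model"] = (time.perf_counter() - t0) / 60.0
    return rows


def _write_heatmaps(cfg, mtm, source, seed_dir):
    from PIL import Image

    cls_tasks = [tc.name for tc in cfg.tasks if tc.kind == "classification"]
    if not cls_tasks:
        return
    xte = source.images_for("test")[:cfg.gradcam_examples]
    for i, img in enumerate(xte):
        amap = grad_cam(mtm, cls_tasks[0], img)
        arr = np.round(amap.heatmap * 255).astype(np.uint8)
        Image.fromarray(arr).save(seed_dir / f"heatmap_{i:03d}_{amap.winning_class}.png")
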