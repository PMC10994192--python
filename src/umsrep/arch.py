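"""Declarative layer/architecture specs, model construction, parameter accounting.

An :class:`ArchitectureSpec` is an ordered list of :class:`LayerSpec` entries
plus an input shape.  The same spec drives two independent routes:

* :func:`count_parameters` — closed-form trainable-parameter arithmetic
  (convolutions contribute ``(kh*kw*c_in + 1) * c_out``, dense layers
  ``(c_in + 1) * c_out``, batch norm ``2 * channels``; everything else zero);
* :func:`build_network` — an executable ``umsrep.nn.Sequential`` whose
  enumerated parameter arrays must agree with the closed form.

Budget reports compare a "proposed" shared-backbone grouping against a
"baseline" separate-models grouping and express the saving as a percentage
reduction in trainable parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import nn

KINDS = {"conv2d", "batch_norm", "relu", "upsample2x", "gap", "fc", "dropout",
         "softmax", "sigmoid"}


class ArchError(ValueError):
    """Raised for inconsistent or invalid architecture specifications."""


@dataclass
class LayerSpec:
    kind: str
    kernel: tuple[int, int] | None = None
    stride: int = 1
    dilation: int = 1
    channels_in: int | None = None
    channels_out: int | None = None
    padding: str = "same"
    rate: float | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ArchError(f"unknown layer kind {self.kind!r}")
        if isinstance(self.kernel, int):
            self.kernel = (self.kernel, self.kernel)
        if self.kernel is not None:
            self.kernel = tuple(int(k) for k in self.kernel)
        if self.kind == "conv2d":
            if None in (self.kernel, self.channels_in, self.channels_out):
                raise ArchError("conv2d needs kernel, channels_in, channels_out")
            if self.stride < 1 or self.dilation < 1:
                raise ArchError("conv2d stride and dilation must be >= 1")
            if self.padding not in ("same", "valid"):
                raise ArchError(f"bad padding {self.padding!r}")
        if self.kind == "fc" and None in (self.channels_in, self.channels_out):
            raise ArchError("fc needs channels_in and channels_out")
        if self.kind == "batch_norm" and self.channels_in is None:
            raise ArchError("batch_norm needs channels_in")
        if self.kind == "dropout":
            if self.rate is None or not (0.0 <= self.rate < 1.0):
                raise ArchError("dropout rate must be in [0, 1)")

    @property
    def n_parameters(self) -> int:
        if self.kind == "conv2d":
            kh, kw = self.kernel
            return (kh * kw * self.channels_in + 1) * self.channels_out
        if self.kind == "fc":
            return (self.channels_in + 1) * self.channels_out
        if self.kind == "batch_norm":
            # trainable scale/shift only; running statistics are not counted
            return 2 * self.channels_in
        return 0


def conv2d(c_in, c_out, kernel=3, stride=1, dilation=1, padding="same"):
    return LayerSpec("conv2d", kernel=kernel, stride=stride, dilation=dilation,
                     channels_in=c_in, channels_out=c_out, padding=padding)


def batch_norm(channels):
    return LayerSpec("batch_norm", channels_in=channels, channels_out=channels)


def fc(c_in, c_out):
    return LayerSpec("fc", channels_in=c_in, channels_out=c_out)


@dataclass
class ArchitectureSpec:
    name: str
    layers: list[LayerSpec]
    input_shape: tuple[int, int, int]  # (H, W, C)

    def validate(self) -> None:
        """Check that channel counts chain consistently through the layers."""
        channels = int(self.input_shape[2])
        spatial = True
        for i, layer in enumerate(self.layers):
            where = f"layer {i} ({layer.kind})"
            if layer.kind == "conv2d":
                if not spatial:
                    raise ArchError(f"{where}: conv2d after spatial collapse")
                if layer.channels_in != channels:
                    raise ArchError(f"{where}: expects {layer.channels_in} channels, "
                                    f"chain provides {channels}")
                channels = layer.channels_out
            elif layer.kind == "batch_norm":
                if layer.channels_in != channels:
                    raise ArchError(f"{where}: batch_norm over {layer.channels_in} "
                                    f"channels, chain provides {channels}")
            elif layer.kind == "gap":
                if not spatial:
                    raise ArchError(f"{where}: gap after spatial collapse")
                spatial = False
            elif layer.kind == "fc":
                if spatial:
                    raise ArchError(f"{where}: fc on spatial input (insert gap first)")
                if layer.channels_in != channels:
                    raise ArchError(f"{where}: fc expects {layer.channels_in}, "
                                    f"chain provides {channels}")
                channels = layer.channels_out
            elif layer.kind == "upsample2x" and not spatial:
                raise ArchError(f"{where}: upsample after spatial collapse")

    def to_dict(self) -> dict:
        return {"name": self.name, "input_shape": list(self.input_shape),
                "layers": [asdict(l) for l in self.layers]}

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        layers = [LayerSpec(**{k: (tuple(v) if k == "kernel" and v is not None else v)
                               for k, v in ld.items()}) for ld in d["layers"]]
        return cls(name=d["name"], layers=layers, input_shape=tuple(d["input_shape"]))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ArchitectureSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def count_parameters(arch: ArchitectureSpec) -> int:
    """Exact trainable-parameter count by the closed-form per-layer formulas."""
    arch.validate()
    return int(sum(l.n_parameters for l in arch.layers))


def build_network(arch: ArchitectureSpec, rng: np.random.Generator | None = None) -> nn.Sequential:
    """Instantiate an executable network from a validated spec."""
    arch.validate()
    layers: list[nn.Layer] = []
    for spec in arch.layers:
        if spec.kind == "conv2d":
            layers.append(nn.Conv2d(spec.channels_in, spec.channels_out,
                                    kernel=spec.kernel[0], stride=spec.stride,
                                    dilation=spec.dilation, padding=spec.padding))
        elif spec.kind == "batch_norm":
            layers.append(nn.BatchNorm(spec.channels_in))
        elif spec.kind == "relu":
            layers.append(nn.ReLU())
        elif spec.kind == "upsample2x":
            layers.append(nn.Upsample2x())
        elif spec.kind == "gap":
            layers.append(nn.GlobalAveragePool())
        elif spec.kind == "fc":
            layers.append(nn.Dense(spec.channels_in, spec.channels_out))
        elif spec.kind == "dropout":
            layers.append(nn.Dropout(spec.rate))
        elif spec.kind == "softmax":
            layers.append(nn.Softmax())
        elif spec.kind == "sigmoid":
            layers.append(nn.Sigmoid())
    net = nn.Sequential(layers)
    if rng is not None:
        net.initialize(rng)
    return net


# ---------------------------------------------------------------------------
# Parameter/compute budget accounting
# ---------------------------------------------------------------------------

@dataclass
class BudgetReport:
    components: dict[str, int]
    groups: dict[str, list[str]]
    totals: dict[str, int]
    reduction_pct: float
    reduction_pct_rounded: int
    times: dict[str, float] = field(default_factory=dict)
    time_totals: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group, names in self.groups.items():
            for name in names:
                rows.append({"group": group, "component": name,
                             "time_min": self.times.get(name, float("nan")),
                             "parameters": self.components[name]})
            rows.append({"group": group, "component": f"{group} total",
                         "time_min": self.time_totals.get(group, float("nan")),
                         "parameters": self.totals[group]})
        df = pd.DataFrame(rows)
        df.attrs["reduction_pct"] = self.reduction_pct
        return df


def budget_report(components: Mapping[str, int],
                  proposed: Sequence[str],
                  baseline: Sequence[str],
                  times: Mapping[str, float] | None = None) -> BudgetReport:
    """Total the parameter budgets of two model groupings and their reduction.

    ``reduction = 100 * (1 - proposed_total / baseline_total)``, reported both
    unrounded and rounded to the nearest integer percent.
    """
    if not proposed or not baseline:
        raise ArchError("groups must be non-empty")
    for name, c in components.items():
        if c < 0:
            raise ArchError(f"negative parameter count for {name!r}")
    missing = [n for n in list(proposed) + list(baseline) if n not in components]
    if missing:
        raise ArchError(f"components missing counts: {missing}")
    totals = {"proposed": int(sum(components[n] for n in proposed)),
              "baseline": int(sum(components[n] for n in baseline))}
    if totals["baseline"] == 0:
        raise ArchError("baseline total is zero; reduction undefined")
    red = 100.0 * (1.0 - totals["proposed"] / totals["baseline"])
    times = dict(times or {})
    time_totals = {}
    if times:
        time_totals = {"proposed": sum(times.get(n, 0.0) for n in proposed),
                       "baseline": sum(times.get(n, 0.0) for n in baseline)}
    return BudgetReport(components=dict(components),
                        groups={"proposed": list(proposed), "baseline": list(baseline)},
                        totals=totals, reduction_pct=red,
                        reduction_pct_rounded=int(round(red)),
                        times=times, time_totals=time_totals)
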