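"""First-order optimizers.

Each optimizer owns per-slot state keyed by position in the (param, grad)
list handed to ``step``; the caller must present parameters in a stable
order.  ``lr`` is a plain mutable attribute so learning-rate schedules
(plateau reduction) can adjust it between epochs.
"""

from __future__ import annotations

import numpy as np


class Optimizer:
    def __init__(self, lr: float):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr = float(lr)
        self._state: list[dict] | None = None

    def _init_state(self, params):
        raise NotImplementedError

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self._state is None:
            self._state = [self._init_slot(p) for p in params]
        if len(params) != len(self._state):
            raise ValueError("parameter list changed between steps")
        for p, g, s in zip(params, grads, self._state):
            self._update(p, g, s)

    def _init_slot(self, p):
        raise NotImplementedError

    def _update(self, p, g, s):
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, lr=1e-2, momentum=0.0):
        super().__init__(lr)
        self.momentum = float(momentum)

    def _init_slot(self, p):
        return {"v": np.zeros_like(p)}

    def _update(self, p, g, s):
        if self.momentum:
            s["v"] = self.momentum * s["v"] + g
            g = s["v"]
        p -= (self.lr * g).astype(p.dtype)


class RMSprop(Optimizer):
    def __init__(self, lr=1e-3, rho=0.9, eps=1e-7):
        super().__init__(lr)
        self.rho, self.eps = float(rho), float(eps)

    def _init_slot(self, p):
        return {"s": np.zeros_like(p, dtype=np.float64)}

    def _update(self, p, g, s):
        s["s"] = self.rho * s["s"] + (1 - self.rho) * np.square(g, dtype=np.float64)
        p -= (self.lr * g / (np.sqrt(s["s"]) + self.eps)).astype(p.dtype)


class Adam(Optimizer):
    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = float(beta1), float(beta2), float(eps)

    def _init_slot(self, p):
        return {"m": np.zeros_like(p, dtype=np.float64),
                "v": np.zeros_like(p, dtype=np.float64), "t": 0}

    def _update(self, p, g, s):
        s["t"] += 1
        s["m"] = self.beta1 * s["m"] + (1 - self.beta1) * g
        s["v"] = self.beta2 * s["v"] + (1 - self.beta2) * np.square(g, dtype=np.float64)
        mhat = s["m"] / (1 - self.beta1 ** s["t"])
        vhat = s["v"] / (1 - self.beta2 ** s["t"])
        p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


_OPTIMIZERS = {"sgd": SGD, "rmsprop": RMSprop, "adam": Adam}


def make_optimizer(name: str, **kwargs) -> Optimizer:
    try:
        cls = _OPTIMIZERS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(_OPTIMIZERS)}") from None
    return cls(**kwargs)
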