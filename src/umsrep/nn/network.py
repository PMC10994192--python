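"""Sequential container: forward/backward chaining, parameter enumeration, state I/O."""

from __future__ import annotations

import hashlib

import numpy as np

from .layers import Layer


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def initialize(self, rng: np.random.Generator) -> "Sequential":
        """Seed all parameters and dropout streams from one generator."""
        from .layers import Dropout

        for layer in self.layers:
            layer.initialize(rng)
            if isinstance(layer, Dropout):
                layer.rng = np.random.default_rng(rng.integers(0, 2**31))
        return self

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def backward_from(self, gout: np.ndarray, last_index: int) -> np.ndarray:
        """Backpropagate starting below layer ``last_index`` (exclusive).

        Used by Grad-CAM to take the gradient of a pre-softmax score."""
        for layer in reversed(self.layers[:last_index]):
            gout = layer.backward(gout)
        return gout

    # -- parameter plumbing -------------------------------------------------
    def named_parameters(self):
        for i, layer in enumerate(self.layers):
            for name in sorted(layer.params):
                yield f"layer{i}.{name}", layer.params[name]

    def parameters(self) -> list[np.ndarray]:
        return [p for _, p in self.named_parameters()]

    def gradients(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            for name in sorted(layer.params):
                out.append(layer.grads[name])
        return out

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.grads = {}

    def n_parameters(self) -> int:
        """Enumerated trainable scalar count (oracle for arch.count_parameters)."""
        return int(sum(p.size for p in self.parameters()))

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        k = 0
        for layer in self.layers:
            for name in sorted(layer.params):
                if layer.params[name].shape != state[k].shape:
                    raise ValueError("state shape mismatch")
                layer.params[name][...] = state[k]
                k += 1
        if k != len(state):
            raise ValueError("state length mismatch")

    def state_hash(self) -> str:
        h = hashlib.sha256()
        for name, p in self.named_parameters():
            h.update(name.encode())
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()

    def astype(self, dtype) -> "Sequential":
        for layer in self.layers:
            layer.astype(dtype)
        return self
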