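"""Minimal feed-forward network primitives with explicit reverse-mode gradients.

Networks here are small MLPs trained on CPU; each layer caches its forward
inputs and accumulates parameter gradients during ``backward``. Gradients must
be zeroed (``Adam.zero_grad``) before each training step.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Linear", "Tanh", "Sequential", "mlp", "Adam", "sigmoid"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable piecewise form
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Linear:
    """Affine map with Glorot-uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init_scale: float = 1.0):
        limit = init_scale * np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.gW += self._x.T @ g
        self.gb += g.sum(axis=0)
        return g @ self.W.T

    def parameters(self):
        return [(self, "W", "gW"), (self, "b", "gb")]


class Tanh:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * (1.0 - self._y ** 2)

    def parameters(self):
        return []


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    # -- checkpoint helpers ------------------------------------------------
    def weight_arrays(self) -> list[np.ndarray]:
        return [getattr(obj, name) for obj, name, _ in self.parameters()]

    def set_weight_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, network expects {len(params)}")
        for (obj, name, _), arr in zip(params, arrays):
            cur = getattr(obj, name)
            if cur.shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}: {cur.shape} vs {arr.shape}")
            setattr(obj, name, arr.astype(float).copy())


def mlp(sizes, rng: np.random.Generator) -> Sequential:
    """Build Linear/Tanh stack; the final layer is linear (no activation)."""
    if len(sizes) < 2:
        raise ValueError("mlp needs at least input and output sizes")
    layers: list = []
    for i in range(len(sizes) - 1):
        layers.append(Linear(sizes[i], sizes[i + 1], rng))
        if i < len(sizes) - 2:
            layers.append(Tanh())
    return Sequential(layers)


class Adam:
    """Adam over the parameters of one or more modules."""

    def __init__(self, modules, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = [p for m in modules for p in m.parameters()]
        self.m = [np.zeros_like(getattr(obj, name)) for obj, name, _ in self.params]
        self.v = [np.zeros_like(getattr(obj, name)) for obj, name, _ in self.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def zero_grad(self) -> None:
        for obj, _, gname in self.params:
            getattr(obj, gname)[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for i, (obj, name, gname) in enumerate(self.params):
            g = getattr(obj, gname)
            self.m[i] = b1 * self.m[i] + (1.0 - b1) * g
            self.v[i] = b2 * self.v[i] + (1.0 - b2) * g * g
            mhat = self.m[i] / bias1
            vhat = self.v[i] / bias2
            getattr(obj, name)[...] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
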