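"""Minimal feed-forward machinery for the projection heads.

The models here are 1–3 layer MLPs trained with Adam, so the forward and
backward passes are written directly in numpy.  Everything is float64 and
seed-deterministic: identical inputs and seeds reproduce identical parameter
trajectories bit for bit.
"""

from __future__ import annotations

import copy

import numpy as np

__all__ = ["MLP", "Adam"]


class MLP:
    """Linear layers with ReLU between them (no activation after the last).

    Weights use fan-in-scaled uniform initialisation U(−1/√fan_in, 1/√fan_in)
    drawn from the supplied generator; biases start at zero.  A nonzero random
    bias would add one shared direction to every output, which after the L2
    normalisation downstream manufactures spurious pairwise similarity in
    untrained heads.
    """

    def __init__(self, dims: list[int], rng: np.random.Generator):
        if len(dims) < 2:
            raise ValueError("need at least input and output dimensions")
        self.dims = list(dims)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for din, dout in zip(dims[:-1], dims[1:]):
            bound = 1.0 / np.sqrt(din)
            self.W.append(rng.uniform(-bound, bound, size=(din, dout)))
            self.b.append(np.zeros(dout))

    @property
    def n_layers(self) -> int:
        return len(self.W)

    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def set_params(self, params: list[np.ndarray]) -> None:
        k = len(self.W)
        self.W = [p.copy() for p in params[:k]]
        self.b = [p.copy() for p in params[k:]]

    def copy(self) -> "MLP":
        return copy.deepcopy(self)

    def forward(self, X: np.ndarray):
        """Return (output, cache) where cache holds per-layer inputs and
        pre-activations for the backward pass."""
        h = np.asarray(X, dtype=float)
        inputs, preacts = [], []
        for li in range(self.n_layers):
            inputs.append(h)
            a = h @ self.W[li] + self.b[li]
            preacts.append(a)
            h = np.maximum(a, 0.0) if li < self.n_layers - 1 else a
        return h, (inputs, preacts)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    def backward(self, cache, grad_out: np.ndarray) -> list[np.ndarray]:
        """Gradients w.r.t. params (same ordering as :meth:`params`)."""
        inputs, preacts = cache
        gW = [None] * self.n_layers
        gb = [None] * self.n_layers
        g = grad_out
        for li in range(self.n_layers - 1, -1, -1):
            if li < self.n_layers - 1:
                g = g * (preacts[li] > 0.0)
            gW[li] = inputs[li].T @ g
            gb[li] = g.sum(axis=0)
            if li > 0:
                g = g @ self.W[li].T
        return gW + gb


class Adam:
    """Adaptive-moment gradient descent over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
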