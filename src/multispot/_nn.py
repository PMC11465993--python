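"""Minimal fully-connected residual network with Adam and cosine annealing.

A deliberately small, dependency-free network engine sufficient for
15x15 single-channel spot crops: an input projection, ``n_blocks``
two-layer residual blocks (the skip connections fuse low- and
high-dimensional features, the property that motivates residual backbones
for this task), and a linear head. Everything is float32 numpy; training
is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ResidualMLP", "AdamState", "cosine_lr", "softmax"]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _he_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)).astype(np.float32)


class ResidualMLP:
    """Input -> Linear+ReLU -> [residual block]*n -> Linear head.

    Each block computes ``relu(x + W2 relu(W1 x + b1) + b2)``.
    """

    def __init__(self, in_dim: int, out_dim: int, hidden: int = 256,
                 n_blocks: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.in_dim, self.out_dim = int(in_dim), int(out_dim)
        self.hidden, self.n_blocks = int(hidden), int(n_blocks)
        self.params: dict[str, np.ndarray] = {}
        self.params["W_in"] = _he_init(rng, in_dim, hidden)
        self.params["b_in"] = np.zeros(hidden, dtype=np.float32)
        for k in range(n_blocks):
            self.params[f"W{k}a"] = _he_init(rng, hidden, hidden)
            self.params[f"b{k}a"] = np.zeros(hidden, dtype=np.float32)
            self.params[f"W{k}b"] = _he_init(rng, hidden, hidden)
            self.params[f"b{k}b"] = np.zeros(hidden, dtype=np.float32)
        self.params["W_out"] = _he_init(rng, hidden, out_dim)
        self.params["b_out"] = np.zeros(out_dim, dtype=np.float32)

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        P = self.params
        x = np.ascontiguousarray(x, dtype=np.float32)
        h = x @ P["W_in"] + P["b_in"]
        m_in = h > 0
        h = h * m_in
        if cache is not None:
            cache["x"], cache["m_in"] = x, m_in
            cache["h_in"] = h
        for k in range(self.n_blocks):
            a = h @ P[f"W{k}a"] + P[f"b{k}a"]
            ma = a > 0
            a = a * ma
            z = h + a @ P[f"W{k}b"] + P[f"b{k}b"]
            mz = z > 0
            hz = z * mz
            if cache is not None:
                cache[f"h{k}"], cache[f"a{k}"] = h, a
                cache[f"ma{k}"], cache[f"mz{k}"] = ma, mz
            h = hz
        if cache is not None:
            cache["h_last"] = h
        return h @ P["W_out"] + P["b_out"]

    def backward(self, cache: dict, dout: np.ndarray) -> dict[str, np.ndarray]:
        P = self.params
        g: dict[str, np.ndarray] = {}
        h_last = cache["h_last"]
        g["W_out"] = h_last.T @ dout
        g["b_out"] = dout.sum(axis=0)
        dh = dout @ P["W_out"].T
        for k in range(self.n_blocks - 1, -1, -1):
            dz = dh * cache[f"mz{k}"]
            g[f"b{k}b"] = dz.sum(axis=0)
            a = cache[f"a{k}"]
            g[f"W{k}b"] = a.T @ dz
            da = (dz @ P[f"W{k}b"].T) * cache[f"ma{k}"]
            g[f"b{k}a"] = da.sum(axis=0)
            h = cache[f"h{k}"]
            g[f"W{k}a"] = h.T @ da
            dh = dz + da @ P[f"W{k}a"].T
        dh = dh * cache["m_in"]
        g["W_in"] = cache["x"].T @ dh
        g["b_in"] = dh.sum(axis=0)
        return g

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        meta = np.array([self.in_dim, self.out_dim, self.hidden, self.n_blocks])
        return {"__meta__": meta, **{k: v.copy() for k, v in self.params.items()}}

    @classmethod
    def from_state_dict(cls, state: dict) -> "ResidualMLP":
        meta = state["__meta__"]
        net = cls(int(meta[0]), int(meta[1]), int(meta[2]), int(meta[3]))
        for k in net.params:
            net.params[k] = np.asarray(state[k], dtype=np.float32)
        return net


class AdamState:
    """Adam with decoupled L2 weight decay (applied to W matrices only)."""

    def __init__(self, params: dict[str, np.ndarray], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             lr: float, weight_decay: float = 0.0) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for k, p in params.items():
            gk = grads[k]
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1 - b1) * gk
            v *= b2
            v += (1 - b2) * gk * gk
            upd = (m / c1) / (np.sqrt(v / c2) + self.eps)
            if weight_decay and k.startswith("W"):
                upd = upd + weight_decay * p
            p -= np.float32(lr) * upd


def cosine_lr(epoch: int, n_epochs: int, lr_initial: float, lr_final: float) -> float:
    """Cosine annealing from ``lr_initial`` to ``lr_final`` over the run."""
    if n_epochs <= 1:
        return lr_initial
    frac = epoch / (n_epochs - 1)
    return lr_final + 0.5 * (lr_initial - lr_final) * (1.0 + np.cos(np.pi * frac))
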