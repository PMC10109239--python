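"""Minimal numpy neural-network primitives: Adam, Glorot init, an MLP.

Full-batch training on graphs of a few thousand nodes keeps everything
dense, so closed-form backprop is exact and fast; no autodiff framework
is involved.
"""

from __future__ import annotations

import numpy as np

BCE_EPS = 1e-7


def sigmoid(t: np.ndarray) -> np.ndarray:
    out = np.empty_like(t, dtype=np.float64)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def bce(p, y) -> float:
    """Binary cross-entropy with probability clamped to [eps, 1-eps]."""
    p = np.clip(np.asarray(p, dtype=np.float64), BCE_EPS, 1.0 - BCE_EPS)
    y = np.asarray(y, dtype=np.float64)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Adam:
    """Adam over a list of parameter arrays, updated in place."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class Discriminator:
    """Feed-forward probe: k -> 64 -> 32 -> 1, leaky-ReLU hidden, sigmoid out.

    Distinguishes embedding rows from reference Gaussian samples; its
    input gradient carries the generator signal back into the encoder.
    """

    SLOPE = 0.2

    def __init__(self, k: int, rng: np.random.Generator,
                 hidden: tuple[int, int] = (64, 32)):
        h1, h2 = hidden
        self.W1 = glorot_uniform(rng, k, h1)
        self.b1 = np.zeros(h1)
        self.W2 = glorot_uniform(rng, h1, h2)
        self.b2 = np.zeros(h2)
        self.W3 = glorot_uniform(rng, h2, 1)
        self.b3 = np.zeros(1)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3]

    def _leaky(self, t):
        return np.where(t > 0, t, self.SLOPE * t)

    def forward(self, X: np.ndarray):
        a1 = X @ self.W1 + self.b1
        h1 = self._leaky(a1)
        a2 = h1 @ self.W2 + self.b2
        h2 = self._leaky(a2)
        a3 = h2 @ self.W3 + self.b3
        p = sigmoid(a3)[:, 0]
        return p, (X, a1, h1, a2, h2)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    def backward(self, cache, dL_da3: np.ndarray):
        """Backprop from the pre-sigmoid output; returns (param grads, dL/dX)."""
        X, a1, h1, a2, h2 = cache
        d3 = dL_da3[:, None]
        gW3 = h2.T @ d3
        gb3 = d3.sum(axis=0)
        dh2 = d3 @ self.W3.T
        d2 = dh2 * np.where(a2 > 0, 1.0, self.SLOPE)
        gW2 = h1.T @ d2
        gb2 = d2.sum(axis=0)
        dh1 = d2 @ self.W2.T
        d1 = dh1 * np.where(a1 > 0, 1.0, self.SLOPE)
        gW1 = X.T @ d1
        gb1 = d1.sum(axis=0)
        dX = d1 @ self.W1.T
        return [gW1, gb1, gW2, gb2, gW3, gb3], dX
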