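"""Minimal feed-forward building blocks with explicit reverse-mode gradients.

Layers store parameters and accumulate gradients in place; ``forward``
returns the output together with an opaque cache that must be handed back
to ``backward``. Keeping the cache external (rather than on the layer) lets
one layer stack be applied twice per step with shared weights -- the drug
encoder runs on both the record's drug and the sampled negative drug, and
gradients from the two passes simply accumulate.

Convolutions are expressed as im2col + GEMM so the heavy lifting stays in
BLAS. Analytic gradients are checked against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Dense",
    "Conv1d",
    "relu_forward",
    "relu_backward",
    "global_max_pool_forward",
    "global_max_pool_backward",
    "dropout_forward",
    "dropout_backward",
    "Adam",
]


class Dense:
    """Affine map ``y = x @ W + b``.

    Weights use He-scaled uniform init (limit sqrt(6/fan_in)): the encoder
    and head stacks are 5-6 ReLU layers deep, and weaker scaling attenuates
    the forward signal enough to waste most of a short training budget.
    Biases use the smaller fan-in-scaled limit.
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype):
        limit = 1.0 / np.sqrt(n_in)
        self.W = rng.uniform(
            -limit * np.sqrt(6.0), limit * np.sqrt(6.0), size=(n_in, n_out)
        ).astype(dtype)
        self.b = rng.uniform(-limit, limit, size=n_out).astype(dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray):
        return x @ self.W + self.b, x

    def backward(self, g: np.ndarray, cache: np.ndarray) -> np.ndarray:
        self.dW += cache.T @ g
        self.db += g.sum(axis=0)
        return g @ self.W.T


class Conv1d:
    """Valid 1-D convolution over (batch, positions, channels) input.

    Weights have shape (kernel, c_in, c_out); output length is
    ``positions - kernel + 1``.
    """

    def __init__(
        self, kernel: int, c_in: int, c_out: int, rng: np.random.Generator, dtype
    ):
        self.kernel = kernel
        limit = 1.0 / np.sqrt(kernel * c_in)
        self.W = rng.uniform(
            -limit * np.sqrt(6.0), limit * np.sqrt(6.0), size=(kernel, c_in, c_out)
        ).astype(dtype)
        self.b = rng.uniform(-limit, limit, size=c_out).astype(dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray):
        B, L, c_in = x.shape
        K = self.kernel
        if K > L:
            raise ValueError(f"kernel {K} longer than sequence axis {L}")
        # windows: (B, T, c_in, K) -> (B, T, K, c_in) for a single GEMM
        win = sliding_window_view(x, K, axis=1).transpose(0, 1, 3, 2)
        T = L - K + 1
        flat = np.ascontiguousarray(win).reshape(B * T, K * c_in)
        out = flat @ self.W.reshape(K * c_in, -1) + self.b
        return out.reshape(B, T, -1), (x, flat)

    def backward(self, g: np.ndarray, cache) -> np.ndarray:
        x, flat = cache
        B, L, c_in = x.shape
        K = self.kernel
        T = L - K + 1
        c_out = self.W.shape[2]
        gflat = g.reshape(B * T, c_out)
        self.dW += (flat.T @ gflat).reshape(K, c_in, c_out)
        self.db += gflat.sum(axis=0)
        # full correlation of upstream grad with the flipped kernel
        gpad = np.zeros((B, T + 2 * (K - 1), c_out), dtype=g.dtype)
        gpad[:, K - 1 : K - 1 + T] = g
        gwin = sliding_window_view(gpad, K, axis=1)  # (B, L, c_out, K)
        gwin = gwin[..., ::-1].transpose(0, 1, 3, 2)  # (B, L, K, c_out)
        gw_flat = np.ascontiguousarray(gwin).reshape(B * L, K * c_out)
        dx = gw_flat @ self.W.transpose(0, 2, 1).reshape(K * c_out, c_in)
        return dx.reshape(B, L, c_in)


def relu_forward(x: np.ndarray):
    mask = x > 0
    return x * mask, mask


def relu_backward(g: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return g * mask


def global_max_pool_forward(x: np.ndarray):
    """Max over the position axis of (batch, positions, channels)."""
    idx = x.argmax(axis=1)
    out = np.take_along_axis(x, idx[:, None, :], axis=1)[:, 0, :]
    return out, (idx, x.shape)


def global_max_pool_backward(g: np.ndarray, cache) -> np.ndarray:
    idx, shape = cache
    dx = np.zeros(shape, dtype=g.dtype)
    np.put_along_axis(dx, idx[:, None, :], g[:, None, :], axis=1)
    return dx


def dropout_forward(x: np.ndarray, rate: float, rng: np.random.Generator):
    """Inverted dropout; identity when rate == 0."""
    if rate <= 0.0:
        return x, None
    keep = (rng.random(x.shape) >= rate).astype(x.dtype) / (1.0 - rate)
    return x * keep, keep


def dropout_backward(g: np.ndarray, keep) -> np.ndarray:
    return g if keep is None else g * keep


class Adam:
    """Adam optimizer updating parameter arrays in place."""

    def __init__(self, params, grads, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.grads = grads
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grads(self) -> None:
        for g in self.grads:
            g[...] = 0.0
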