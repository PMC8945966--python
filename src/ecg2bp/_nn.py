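"""Minimal numpy building blocks for the 1D-CNN regressor.

Forward/backward passes for same-padded 1-D convolution (im2col), max
pooling, global average pooling, dense layers and ReLU, plus an Adam
optimizer.  Parameters and activations are float32 (adequate precision for
SGD, twice the throughput of float64); runs are deterministic for a fixed
seed on a given platform.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def conv1d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """x: (N, C, L); W: (F, C, K) with K odd; b: (F,). Same padding, stride 1."""
    N, C, L = x.shape
    F, _, K = W.shape
    pad = K // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    cols = sliding_window_view(xp, K, axis=2)           # (N, C, L, K)
    cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(N, L, C * K)
    out = cols @ W.reshape(F, C * K).T + b              # (N, L, F)
    return out.transpose(0, 2, 1), (cols, x.shape)


def conv1d_backward(dout: np.ndarray, W: np.ndarray, cache):
    cols, xshape = cache
    N, C, L = xshape
    F, _, K = W.shape
    pad = K // 2
    d = dout.transpose(0, 2, 1)                         # (N, L, F)
    dW = (d.reshape(N * L, F).T @ cols.reshape(N * L, C * K)).reshape(F, C, K)
    db = d.sum(axis=(0, 1))
    dcols = (d @ W.reshape(F, C * K)).reshape(N, L, C, K).transpose(0, 2, 1, 3)
    dxp = np.zeros((N, C, L + 2 * pad), dtype=dout.dtype)
    for k in range(K):
        dxp[:, :, k:k + L] += dcols[:, :, :, k]
    return dxp[:, :, pad:pad + L], dW, db


def maxpool_forward(x: np.ndarray, size: int = 2):
    N, C, L = x.shape
    xr = x.reshape(N, C, L // size, size)
    idx = xr.argmax(axis=3)
    return xr.max(axis=3), (idx, x.shape, size)


def maxpool_backward(dout: np.ndarray, cache):
    idx, shape, size = cache
    N, C, L = shape
    dxr = np.zeros((N, C, L // size, size), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=3)
    return dxr.reshape(N, C, L)


def gap_forward(x: np.ndarray):
    """Global average pool over the time axis: (N, C, L) -> (N, C)."""
    return x.mean(axis=2), x.shape


def gap_backward(dout: np.ndarray, shape):
    N, C, L = shape
    return np.repeat(dout[:, :, None], L, axis=2) / L


def dense_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    return x @ W + b, x


def dense_backward(dout: np.ndarray, W: np.ndarray, x: np.ndarray):
    return dout @ W.T, x.T @ dout, dout.sum(axis=0)


def relu_forward(x: np.ndarray):
    return np.maximum(x, 0.0), x > 0


def relu_backward(dout: np.ndarray, mask: np.ndarray):
    return dout * mask


class Adam:
    """Adaptive-moment estimation over a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray], clip_norm: float | None = 5.0) -> None:
        if clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
            if total > clip_norm:
                scale = clip_norm / total
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
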