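"""Minimal NumPy feed-forward core for the splice-site CNN.

The network is small (two valid-mode 1D convolutions, ReLU, width-2 max
pooling, one dense softmax head), so forward and backward passes are written
directly against NumPy with im2col-style convolutions.  Analytic gradients are
verified against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def conv1d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Valid-mode 1D convolution (cross-correlation).

    x: (B, C_in, L); w: (C_out, C_in, K); b: (C_out,)
    returns out (B, C_out, L-K+1) and a cache for backward.
    """
    k = w.shape[2]
    # (B, C_in, L_out, K) sliding view, no copy
    cols = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)
    out = np.einsum("fck,bcpk->bfp", w, cols, optimize=True) + b[None, :, None]
    return out, (x, cols, w)


def conv1d_backward(dout: np.ndarray, cache):
    x, cols, w = cache
    db = dout.sum(axis=(0, 2))
    dw = np.einsum("bfp,bcpk->fck", dout, cols, optimize=True)
    # scatter-add dout*w back over the sliding windows
    dx = np.zeros_like(x)
    k = w.shape[2]
    dcols = np.einsum("bfp,fck->bcpk", dout, w, optimize=True)
    for kk in range(k):
        dx[:, :, kk : kk + dcols.shape[2]] += dcols[:, :, :, kk]
    return dx, dw, db


def relu_forward(x):
    out = np.maximum(x, 0.0)
    return out, (x > 0)


def relu_backward(dout, mask):
    return dout * mask


def maxpool1d_forward(x: np.ndarray, size: int = 2):
    """Non-overlapping max pooling along the last axis; truncates the remainder."""
    b, c, l = x.shape
    lo = l // size
    xr = x[:, :, : lo * size].reshape(b, c, lo, size)
    arg = xr.argmax(axis=3)
    out = np.take_along_axis(xr, arg[..., None], axis=3)[..., 0]
    return out, (x.shape, size, arg)


def maxpool1d_backward(dout: np.ndarray, cache):
    shape, size, arg = cache
    b, c, l = shape
    lo = l // size
    dxr = np.zeros((b, c, lo, size), dtype=dout.dtype)
    np.put_along_axis(dxr, arg[..., None], dout[..., None], axis=3)
    dx = np.zeros(shape, dtype=dout.dtype)
    dx[:, :, : lo * size] = dxr.reshape(b, c, lo * size)
    return dx


def dense_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """x: (B, F); w: (O, F); b: (O,)"""
    return x @ w.T + b, (x, w)


def dense_backward(dout, cache):
    x, w = cache
    return dout @ w, dout.T @ x, dout.sum(axis=0)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean negative log-likelihood of integer labels y under row-wise probs."""
    p = np.clip(probs[np.arange(len(y)), y], 1e-12, None)
    return float(-np.log(p).mean())


def softmax_ce_backward(probs: np.ndarray, y: np.ndarray) -> np.ndarray:
    """d(mean CE)/d logits for a softmax + cross-entropy head."""
    g = probs.copy()
    g[np.arange(len(y)), y] -= 1.0
    return g / len(y)


class Adam:
    """Adam optimizer over a dict of named parameter arrays (updates in place)."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
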