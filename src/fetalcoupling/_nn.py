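"""Minimal 1-D CNN engine: FFT convolution, batch-norm, dense, ADAM.

Layers operate on arrays of shape ``(batch, channels, length)`` and
implement explicit forward/backward passes; gradients are verified against
finite differences in the test suite.  Convolutions use 'same' padding and
stride 1 and are evaluated in the frequency domain (kernels here are long
-- hundreds of samples -- so FFT products are far cheaper than direct
sliding dot products).  The default dtype is float32; float64 is available
for gradient checking.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sfft

__all__ = ["Conv1dSame", "BatchNorm1d", "ReLU", "Dense", "Adam", "softmax", "weighted_xent"]


class Layer:
    """Base: parameter/gradient dicts plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1dSame(Layer):
    """1-D cross-correlation, stride 1, 'same' (zero) padding, with bias.

    Output ``y[b,o,t] = bias[o] + sum_{i,j} w[o,i,j] x[b,i,t-pl+j]`` with
    ``pl = (k-1)//2``; x is zero outside [0, L).  Forward and both backward
    products are computed via real FFTs of length >= L + k - 1, which makes
    them exact (no circular aliasing).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        if kernel < 1:
            raise ValueError(f"kernel must be >= 1, got {kernel}")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.dtype = dtype
        limit = np.sqrt(6.0 / (c_in * kernel + c_out * kernel))  # Glorot uniform
        self.params["w"] = rng.uniform(-limit, limit, size=(c_out, c_in, kernel)).astype(dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)
        self._cache = None

    def _plan(self, L: int) -> tuple[int, int, int]:
        nfft = sfft.next_fast_len(L + self.k - 1, real=True)
        pl = (self.k - 1) // 2
        off = self.k - 1 - pl
        return nfft, pl, off

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        B, c_in, L = x.shape
        if c_in != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c_in}")
        if self.k > L:
            raise ValueError(f"kernel ({self.k}) longer than input ({L})")
        nfft, pl, off = self._plan(L)
        xf = sfft.rfft(x, nfft)
        wf_flip = sfft.rfft(self.params["w"][:, :, ::-1], nfft)
        yf = np.einsum("bif,oif->bof", xf, wf_flip)
        y = sfft.irfft(yf, nfft)[:, :, off : off + L]
        y = y.astype(self.dtype) + self.params["b"][None, :, None]
        if training:
            self._cache = (xf, L)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xf, L = self._cache
        nfft, pl, off = self._plan(L)
        gf = sfft.rfft(grad, nfft)
        # grad wrt input: correlate grad with the (unflipped) kernel
        wf = sfft.rfft(self.params["w"], nfft)
        gx = sfft.irfft(np.einsum("bof,oif->bif", gf, wf), nfft)[:, :, pl : pl + L]
        # grad wrt weights: cross-correlation of x with grad at lags j - pl
        cc_f = np.einsum("bif,bof->oif", xf, np.conj(gf))
        cc = sfft.irfft(cc_f, nfft)
        lags = (np.arange(self.k) - pl) % nfft
        self.grads["w"] = cc[:, :, lags].astype(self.dtype)
        self.grads["b"] = grad.sum(axis=(0, 2)).astype(self.dtype)
        return gx.astype(self.dtype)


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length).

    Training uses batch statistics and updates running estimates
    (momentum 0.1, unbiased running variance); inference uses the running
    estimates, so prediction is deterministic and batch-size invariant.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.dtype = dtype
        self.params["gamma"] = np.ones(c, dtype=dtype)
        self.params["beta"] = np.zeros(c, dtype=dtype)
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            M = x.shape[0] * x.shape[2]
            self.running_mean += self.momentum * (mu.astype(np.float64) - self.running_mean)
            unbiased = var * (M / max(M - 1, 1))
            self.running_var += self.momentum * (unbiased.astype(np.float64) - self.running_var)
        else:
            mu = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) * ivar[None, :, None]
        if training:
            self._cache = (xhat, ivar)
        return (self.params["gamma"][None, :, None] * xhat + self.params["beta"][None, :, None]).astype(self.dtype)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, ivar = self._cache
        M = grad.shape[0] * grad.shape[2]
        g_xhat_sum = (grad * xhat).sum(axis=(0, 2))
        g_sum = grad.sum(axis=(0, 2))
        self.grads["gamma"] = g_xhat_sum.astype(self.dtype)
        self.grads["beta"] = g_sum.astype(self.dtype)
        coef = (self.params["gamma"] * ivar / M)[None, :, None]
        gx = coef * (M * grad - g_sum[None, :, None] - xhat * g_xhat_sum[None, :, None])
        return gx.astype(self.dtype)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        y = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Dense(Layer):
    """Fully connected layer on flattened input: y = x @ W + b."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.params["w"] = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(dtype)
        self.params["b"] = np.zeros(n_out, dtype=dtype)
        self.dtype = dtype

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["w"] = (self._x.T @ grad).astype(self.dtype)
        self.grads["b"] = grad.sum(axis=0).astype(self.dtype)
        return (grad @ self.params["w"].T).astype(self.dtype)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_xent(logits: np.ndarray, y: np.ndarray, class_weights: np.ndarray) -> tuple[float, np.ndarray]:
    """Class-weighted softmax cross-entropy (weighted mean over the batch).

    Returns (loss, grad wrt logits).  With unit weights this reduces to the
    plain mean cross-entropy.
    """
    p = softmax(logits.astype(np.float64))
    B = logits.shape[0]
    w = class_weights[y]
    wsum = w.sum()
    loss = float((w * -np.log(np.maximum(p[np.arange(B), y], 1e-300))).sum() / wsum)
    grad = p
    grad[np.arange(B), y] -= 1.0
    grad *= (w / wsum)[:, None]
    return loss, grad.astype(logits.dtype)


class Adam:
    """ADAM optimizer with optional decoupled-from-bias L2 term.

    The L2 term adds ``l2 * w`` to the gradient of every parameter named
    'w' (conv and dense weights), i.e. a (l2/2)||w||^2 penalty; biases and
    batch-norm parameters are not penalized.
    """

    def __init__(self, layers, lr: float = 1e-3, l2: float = 1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [ly for ly in layers if ly.params]
        self.lr, self.l2 = lr, l2
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v, dtype=np.float64) for k, v in ly.params.items()} for ly in self.layers]
        self.v = [{k: np.zeros_like(v, dtype=np.float64) for k, v in ly.params.items()} for ly in self.layers]

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for ly, m, v in zip(self.layers, self.m, self.v):
            for k, p in ly.params.items():
                g = ly.grads[k].astype(np.float64)
                if k == "w" and self.l2:
                    g = g + self.l2 * p
                m[k] = self.beta1 * m[k] + (1.0 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1.0 - self.beta2) * g * g
                update = self.lr * (m[k] / b1c) / (np.sqrt(v[k] / b2c) + self.eps)
                ly.params[k] = (p - update).astype(p.dtype)
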