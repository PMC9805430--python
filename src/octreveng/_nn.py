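"""Minimal CNN engine: batched NCHW layers with explicit forward/backward.

Everything the segmentation network needs is implemented here on plain
numpy arrays: same-padded square convolutions, 2x2 max pooling that
records argmax "switches", 2x2 stride-2 transposed convolutions for
learned upsampling, ReLU, and an Adam optimizer.

Design constraints:

* the max-pool switches and the convolution kernels must be reusable by
  the network-inversion pass (shared weights, unpooling), so pooling
  exposes its switches and convolutions expose a ``transposed_apply``
  (the exact adjoint of the forward linear map, bias excluded);
* gradients must be exact enough to pass finite-difference checks, so
  every layer supports float64 as well as the float32 training default.

The convolution inner loops are numba-compiled: at the small channel
counts this network uses, direct loops vectorized along the contiguous
width axis are an order of magnitude faster than im2col + GEMM on one
core. Arrays are (N, C, H, W); all randomness flows through an explicit
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "Conv2d",
    "UpConv2x2",
    "maxpool2x2",
    "unpool2x2",
    "relu",
    "Adam",
]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0)


# ----------------------------------------------------------------------
# numba convolution kernels (same padding, stride 1, square k)
# ----------------------------------------------------------------------

@njit(fastmath=True, cache=True)
def _conv_fwd(xp, w, b, y, k):
    """y[n,f,h,:] = b[f] + sum_{c,dy,dx} w[f,c,dy,dx] * xp[n,c,h+dy,:+dx]"""
    n_b, c_in, _, _ = xp.shape
    f_out = w.shape[0]
    h_out, w_out = y.shape[2], y.shape[3]
    for n in range(n_b):
        for f in range(f_out):
            acc = y[n, f]
            for h in range(h_out):
                row = acc[h]
                for x in range(w_out):
                    row[x] = b[f]
            for c in range(c_in):
                for dy in range(k):
                    for dx in range(k):
                        wv = w[f, c, dy, dx]
                        for h in range(h_out):
                            src = xp[n, c, h + dy]
                            dst = acc[h]
                            for x in range(w_out):
                                dst[x] += wv * src[x + dx]


@njit(fastmath=True, cache=True)
def _conv_bwd_dw(xp, g, dw, db, k):
    """Weight/bias gradients: dot products of grad rows with input rows."""
    n_b, f_out, h_out, w_out = g.shape
    c_in = xp.shape[1]
    for n in range(n_b):
        for f in range(f_out):
            s = 0.0
            for h in range(h_out):
                gr = g[n, f, h]
                for x in range(w_out):
                    s += gr[x]
            db[f] += s
            for c in range(c_in):
                for dy in range(k):
                    for dx in range(k):
                        acc = 0.0
                        for h in range(h_out):
                            gr = g[n, f, h]
                            src = xp[n, c, h + dy]
                            for x in range(w_out):
                                acc += gr[x] * src[x + dx]
                        dw[f, c, dy, dx] += acc


class Conv2d:
    """Square same-padded stride-1 convolution (cross-correlation).

    Weights are (out_ch, in_ch, k, k); He-initialized from the supplied
    generator.
    """

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 dtype=np.float32):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        fan_in = in_ch * k * k
        self.weight = (rng.standard_normal((out_ch, in_ch, k, k)) *
                       np.sqrt(2.0 / fan_in)).astype(dtype)
        self.bias = np.zeros(out_ch, dtype=dtype)
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)
        self._xp: np.ndarray | None = None

    def _pad(self, x):
        p = self.k // 2
        if p == 0:
            return np.ascontiguousarray(x)
        return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        xp = self._pad(x)
        if keep:
            self._xp = xp
        y = np.empty((n, self.out_ch, h, w), dtype=x.dtype)
        _conv_fwd(xp, self.weight.astype(x.dtype, copy=False),
                  self.bias.astype(x.dtype, copy=False), y, self.k)
        return y

    def backward(self, dy: np.ndarray, need_input_grad: bool = True):
        if self._xp is None:
            raise RuntimeError("backward called before forward")
        dy = np.ascontiguousarray(dy)
        _conv_bwd_dw(self._xp, dy, self.grad_weight, self.grad_bias, self.k)
        self._xp = None
        if not need_input_grad:
            return None
        return self.transposed_apply(dy)

    def transposed_apply(self, s: np.ndarray) -> np.ndarray:
        """Apply the transpose of the forward linear map (no bias).

        This is both the input-gradient of training backprop and the
        shared-weight transposed convolution of the inversion pass. The
        adjoint of a same-padded correlation is the same-padded correlation
        with spatially flipped kernels and in/out channels swapped, so the
        forward kernel is reused in gather form (no scatter-adds).
        """
        n, f, h, w = s.shape
        if f != self.out_ch:
            raise ValueError(f"expected {self.out_ch} channels, got {f}")
        wt = np.ascontiguousarray(
            self.weight[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        ).astype(s.dtype, copy=False)
        p = self.k // 2
        sp = np.pad(s, ((0, 0), (0, 0), (p, p), (p, p))) if p else \
            np.ascontiguousarray(s)
        out = np.empty((n, self.in_ch, h, w), dtype=s.dtype)
        _conv_fwd(sp, wt, np.zeros(self.in_ch, dtype=s.dtype), out, self.k)
        return out

    @property
    def params(self):
        return [(self.weight, self.grad_weight), (self.bias, self.grad_bias)]


class UpConv2x2:
    """2x2 stride-2 transposed convolution (learned upsampling).

    Kernel and stride coincide, so output windows never overlap and both
    directions are plain einsums. Weights are (in_ch, out_ch, 2, 2).
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in = in_ch * 4
        self.weight = (rng.standard_normal((in_ch, out_ch, 2, 2)) *
                       np.sqrt(2.0 / fan_in)).astype(dtype)
        self.bias = np.zeros(out_ch, dtype=dtype)
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        if keep:
            self._x = x
        wt = self.weight.astype(x.dtype, copy=False)
        y = np.einsum("nchw,cfab->nfhawb", x, wt, optimize=True)
        y = np.ascontiguousarray(y).reshape(n, self.out_ch, 2 * h, 2 * w)
        return y + self.bias.astype(x.dtype, copy=False)[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._x is None:
            raise RuntimeError("backward called before forward")
        n, f, h2, w2 = dy.shape
        dyr = dy.reshape(n, f, h2 // 2, 2, w2 // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self.grad_weight += np.einsum("nfhwab,nchw->cfab", dyr, self._x,
                                      optimize=True)
        self.grad_bias += dy.sum(axis=(0, 2, 3))
        dx = np.einsum("nfhwab,cfab->nchw", dyr,
                       self.weight.astype(dy.dtype, copy=False), optimize=True)
        self._x = None
        return np.ascontiguousarray(dx)

    def transposed_apply(self, s: np.ndarray) -> np.ndarray:
        """Reverse map: stride-2 2x2 correlation with the shared kernel."""
        n, f, h2, w2 = s.shape
        if f != self.out_ch:
            raise ValueError(f"expected {self.out_ch} channels, got {f}")
        sr = s.reshape(n, f, h2 // 2, 2, w2 // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        out = np.einsum("nfhwab,cfab->nchw", sr,
                        self.weight.astype(s.dtype, copy=False), optimize=True)
        return np.ascontiguousarray(out)

    @property
    def params(self):
        return [(self.weight, self.grad_weight), (self.bias, self.grad_bias)]


def maxpool2x2(x: np.ndarray):
    """2x2 max pooling. Returns (pooled, switches).

    ``switches`` holds, for every pooled element, the flat index (0..3,
    row-major within its 2x2 window) of the position that carried the
    maximum -- the information needed to invert the pooling exactly.
    """
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 needs even spatial dims")
    win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = np.ascontiguousarray(win).reshape(n, c, h // 2, w // 2, 4)
    switches = win.argmax(axis=-1).astype(np.int8)
    pooled = np.take_along_axis(win, switches[..., None].astype(np.intp),
                                axis=-1)[..., 0]
    return pooled, switches


def unpool2x2(pooled: np.ndarray, switches: np.ndarray, out_shape=None) -> np.ndarray:
    """Place each pooled value back at its recorded position, zero elsewhere."""
    n, c, hp, wp = pooled.shape
    if switches.shape != (n, c, hp, wp):
        raise ValueError("switch tensor shape does not match pooled input")
    if out_shape is not None and tuple(out_shape) != (2 * hp, 2 * wp):
        raise ValueError("out_shape inconsistent with 2x2 unpooling")
    out = np.zeros((n, c, hp, wp, 4), dtype=pooled.dtype)
    np.put_along_axis(out, switches[..., None].astype(np.intp),
                      pooled[..., None], axis=-1)
    out = out.reshape(n, c, hp, wp, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return np.ascontiguousarray(out).reshape(n, c, 2 * hp, 2 * wp)


class Adam:
    """Adam with the conventional beta/epsilon defaults."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)  # list of (value, grad) array pairs
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0
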