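"""Minimal CNN building blocks with explicit forward/backward passes.

The network this package implements is small and fixed in topology, so
instead of a general autograd graph each layer is a plain object with a
``forward`` and a ``backward`` method and explicit parameter/gradient
dictionaries.  Everything heavy is expressed as BLAS matmuls on float32
arrays, which keeps full training runs tractable on a single CPU and makes
every operation bit-reproducible for a fixed seed.

Layout convention (chosen so that all large copies and window extractions
run along contiguous axes, which dominates single-core throughput):

* before the spatial convolution, activations are ``[batch, eeg_channel,
  time, map]`` with the filter-bank map axis last;
* from the spatial convolution on, activations are ``[batch, map, time]``.

The temporal filter bank is realized as one im2col of width ``max(kernel
lengths)`` shared by all branches; each branch multiplies a column slice of
it, so "same"-padded parallel convolutions of different lengths cost one
window extraction and four thin GEMMs.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32
# clamp for the log non-linearity; far below any post-batch-norm band power
LOG_FLOOR = 1e-30


class _Workspace:
    """Per-layer reusable buffers.

    Allocating hundreds of MB per mini-batch costs more in page faults than
    the arithmetic on a single core, so each layer keeps its large scratch
    arrays alive between calls.  Buffers are only valid until the same
    layer's next forward/backward, which the training loop respects.
    """

    def __init__(self) -> None:
        self._bufs: dict[tuple, np.ndarray] = {}

    def get(self, key: str, shape: tuple[int, ...], dtype=DTYPE,
            zero: bool = False) -> np.ndarray:
        # keyed by shape too: train and eval batches of different sizes
        # alternate, and each should keep its own buffer
        full_key = (key, shape, np.dtype(dtype).str)
        buf = self._bufs.get(full_key)
        if buf is None:
            buf = np.empty(shape, dtype=dtype)
            self._bufs[full_key] = buf
        if zero:
            buf.fill(0)
        return buf


class Layer:
    """Base layer: parameter dict, gradient dict, forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._ws = _Workspace()

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class FusedTemporalConv(Layer):
    """Parallel multiscale temporal filter bank.

    Branch ``i`` convolves the input along time with ``f_t`` filters of
    length ``kernels[i]`` and "same" zero padding
    (``pad_left = (k-1)//2``); branch outputs are concatenated on the map
    axis in branch order.  All branches read column slices of a single
    shared im2col buffer of width ``max(kernels)``, at offsets that align
    each branch's own "same" padding.  No bias (a batch norm follows).

    Input ``[B, C, T]`` -> output ``[B, C, T, n_branches * f_t]``.
    """

    def __init__(self, kernels: tuple[int, ...], f_t: int) -> None:
        super().__init__()
        self.kernels = tuple(int(k) for k in kernels)
        self.f_t = int(f_t)
        self.k_max = max(self.kernels)
        self.pad_left = (self.k_max - 1) // 2
        self.pad_right = self.k_max - 1 - self.pad_left
        for i, k in enumerate(self.kernels):
            self.params[f"w{i}"] = np.zeros((f_t, k), dtype=DTYPE)
        self._offsets = [self.pad_left - (k - 1) // 2 for k in self.kernels]
        self._cols: np.ndarray | None = None
        self._shape_in: tuple[int, ...] | None = None

    @property
    def n_maps_out(self) -> int:
        return len(self.kernels) * self.f_t

    def _fused_weight(self) -> np.ndarray:
        w = np.zeros((self.n_maps_out, self.k_max), dtype=DTYPE)
        for i, k in enumerate(self.kernels):
            off = self._offsets[i]
            w[i * self.f_t:(i + 1) * self.f_t, off:off + k] = self.params[f"w{i}"]
        return w

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        b, c, t = x.shape
        xp = self._ws.get("xp", (b, c, t + self.k_max - 1), zero=True)
        np.copyto(xp[:, :, self.pad_left:self.pad_left + t], x)
        win = sliding_window_view(xp, self.k_max, axis=2)  # [B, C, T', k]; windows contiguous
        cols = self._ws.get("cols", (b * c * t, self.k_max))
        np.copyto(cols.reshape(b, c, t, self.k_max), win[:, :, :t])
        return cols

    def forward(self, x, training=False, rng=None):
        b, c, t = x.shape
        self._shape_in = x.shape
        cols = self._im2col(x)
        self._cols = cols if training else None
        # one contiguous GEMM feeds all branches
        y = self._ws.get("y", (b * c * t, self.n_maps_out))
        np.matmul(cols, self._fused_weight().T, out=y)
        return y.reshape(b, c, t, self.n_maps_out)

    def backward(self, dy):
        b, c, t = self._shape_in
        dyf = dy.reshape(-1, self.n_maps_out)
        cols = self._cols
        self._cols = None
        dw_fused = dyf.T @ cols  # [maps, k_max]; out-of-support taps discarded below
        for i, k in enumerate(self.kernels):
            off = self._offsets[i]
            self.grads[f"w{i}"] = dw_fused[i * self.f_t:(i + 1) * self.f_t, off:off + k].copy()
        # gradient w.r.t. the input: full correlation with the flipped bank.
        # zt[j] is contiguous over (b, c, t), so the col2im scatter below is a
        # sequence of contiguous axpys.
        w = self._fused_weight()
        zt = self._ws.get("zt", (self.k_max, b * c * t))
        np.matmul(w.T, dyf.T, out=zt)
        zt = zt.reshape(self.k_max, b, c, t)
        tp = t + self.k_max - 1
        dxp = self._ws.get("dxp", (b, c, tp), zero=True)
        for j in range(self.k_max):
            dxp[:, :, j:j + t] += zt[j]
        return np.ascontiguousarray(dxp[:, :, self.pad_left:self.pad_left + t])


class SpatialConv(Layer):
    """Convolution with kernel ``(1, C)`` over all electrodes: a learned
    spatial filter per output map (the CSP analogue).  Valid padding
    collapses the electrode axis; no bias.

    Input ``[B, C, T, F_in]`` -> output ``[B, T, F_S]``; weights
    ``[F_S, F_in, C]``.
    """

    def __init__(self, f_s: int, n_maps_in: int, n_space: int) -> None:
        super().__init__()
        self.f_s, self.n_maps_in, self.n_space = int(f_s), int(n_maps_in), int(n_space)
        self.params["w"] = np.zeros((f_s, n_maps_in, n_space), dtype=DTYPE)
        self._x: np.ndarray | None = None

    def forward(self, x, training=False, rng=None):
        b, c, t, f = x.shape
        self._x = x
        w = self.params["w"]
        y = np.zeros((b * t, self.f_s), dtype=DTYPE)
        for ci in range(c):
            y += x[:, ci].reshape(-1, f) @ w[:, :, ci].T
        return y.reshape(b, t, self.f_s)

    def backward(self, dy):
        x = self._x
        b, c, t, f = x.shape
        dyt = dy.reshape(-1, self.f_s)
        w = self.params["w"]
        dw = np.empty_like(w)
        dx = self._ws.get("dx", x.shape)
        for ci in range(c):
            xc = x[:, ci].reshape(-1, f)
            dw[:, :, ci] = dyt.T @ xc
            dx[:, ci] = (dyt @ w[:, :, ci]).reshape(b, t, f)
        self.grads["w"] = dw
        return dx


class BatchNorm(Layer):
    """Batch normalization of the last (map) axis, statistics over all
    leading axes.  Forward and backward are each a handful of single-pass
    fused expressions of the form ``a*x + b*dy + c``."""

    def __init__(self, n_maps: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.n_maps = int(n_maps)
        self.eps, self.momentum = float(eps), float(momentum)
        self.params["gamma"] = np.ones(n_maps, dtype=DTYPE)
        self.params["beta"] = np.zeros(n_maps, dtype=DTYPE)
        self.running_mean = np.zeros(n_maps, dtype=DTYPE)
        self.running_var = np.ones(n_maps, dtype=DTYPE)
        self._cache: tuple | None = None

    def forward(self, x, training=False, rng=None):
        flat = x.reshape(-1, self.n_maps)
        n = flat.shape[0]
        if training:
            mean = flat.mean(axis=0).astype(np.float64)
            sq = np.einsum("nf,nf->f", flat, flat).astype(np.float64) / n
            var = np.maximum(sq - mean * mean, 0.0)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(DTYPE)
            unbiased = var * (n / max(1, n - 1))
            self.running_var = ((1 - m) * self.running_var + m * unbiased).astype(DTYPE)
        else:
            mean = self.running_mean.astype(np.float64)
            var = self.running_var.astype(np.float64)
        inv = 1.0 / np.sqrt(var + self.eps)
        mean32, inv32 = mean.astype(DTYPE), inv.astype(DTYPE)
        scale = self.params["gamma"] * inv32
        shift = self.params["beta"] - mean32 * scale
        self._cache = (x, mean32, inv32, n, training)
        y = self._ws.get("y", x.shape)
        np.multiply(x, scale, out=y)
        y += shift
        return y

    def backward(self, dy):
        x, mean, inv, n, training = self._cache
        g = self.params["gamma"]
        dyf = dy.reshape(-1, self.n_maps)
        xf = x.reshape(-1, self.n_maps)
        sum_dy = dyf.sum(axis=0)
        sum_dy_x = np.einsum("nf,nf->f", dyf, xf)
        self.grads["beta"] = sum_dy
        dgamma = inv * (sum_dy_x - mean * sum_dy)
        self.grads["gamma"] = dgamma
        p = g * inv
        if not training:
            return dy * p
        q = -p * inv * dgamma / n
        r = -p * sum_dy / n - q * mean
        dx = self._ws.get("dx", dy.shape)
        np.multiply(dy, p, out=dx)
        tmp = self._ws.get("tmp", x.shape)
        np.multiply(x, q, out=tmp)
        dx += tmp
        dx += r
        return dx


class TransposeToMapsFirst(Layer):
    """[B, T, F] -> [B, F, T] (parameter-free relayout after the spatial conv)."""

    def forward(self, x, training=False, rng=None):
        return np.ascontiguousarray(x.transpose(0, 2, 1))

    def backward(self, dy):
        return np.ascontiguousarray(dy.transpose(0, 2, 1))


class Square(Layer):
    def forward(self, x, training=False, rng=None):
        self._x = x
        return x * x

    def backward(self, dy):
        return 2.0 * self._x * dy


class AvgPoolTime(Layer):
    """Average pooling along the last (time) axis, valid padding.

    Output length ``L = (T - length)//stride + 1``; with overlapping windows
    (stride < length) the backward pass scatter-adds ``dy/length`` into each
    window.
    """

    def __init__(self, length: int, stride: int) -> None:
        super().__init__()
        self.length, self.stride = int(length), int(stride)
        self._t_in: int | None = None

    def out_length(self, t: int) -> int:
        if t < self.length:
            raise ValueError(f"pool length {self.length} exceeds input length {t}")
        return (t - self.length) // self.stride + 1

    def forward(self, x, training=False, rng=None):
        b, f, t = x.shape
        self._t_in = t
        l_out = self.out_length(t)
        cs = np.zeros((b, f, t + 1), dtype=np.float64)
        np.cumsum(x, axis=-1, out=cs[:, :, 1:])
        starts = np.arange(l_out) * self.stride
        y = (cs[:, :, starts + self.length] - cs[:, :, starts]) / self.length
        return y.astype(DTYPE)

    def backward(self, dy):
        b, f, l_out = dy.shape
        dx = np.zeros((b, f, self._t_in), dtype=DTYPE)
        g = dy / self.length
        for i in range(l_out):
            s = i * self.stride
            dx[:, :, s:s + self.length] += g[:, :, i:i + 1]
        return dx


class Log(Layer):
    """Natural log with a tiny clamp so exact zeros stay finite."""

    def forward(self, x, training=False, rng=None):
        xc = np.maximum(x, LOG_FLOOR)
        self._xc = xc
        self._mask = x > LOG_FLOOR
        return np.log(xc)

    def backward(self, dy):
        return np.where(self._mask, dy / self._xc, 0.0).astype(DTYPE, copy=False)


class Dropout(Layer):
    """Inverted dropout; active only with ``training=True`` and a generator."""

    def __init__(self, p: float) -> None:
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError(f"dropout p must be in [0,1), got {p}")
        self.p = float(p)
        self._mask: np.ndarray | None = None

    def forward(self, x, training=False, rng=None):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs a random generator")
        keep = (rng.random(x.shape) >= self.p).astype(DTYPE) / (1.0 - self.p)
        self._mask = keep
        return x * keep

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class DenseClassifier(Layer):
    """Convolutional classifier: kernel spans the whole pooled feature map,
    equivalent to a fully connected layer.  Carries a bias of size N_C.

    Input ``[B, F_S, L]`` -> logits ``[B, N_C]``.
    """

    def __init__(self, n_classes: int, f_s: int, l_in: int) -> None:
        super().__init__()
        self.n_classes, self.f_s, self.l_in = int(n_classes), int(f_s), int(l_in)
        self.params["w"] = np.zeros((n_classes, f_s, l_in), dtype=DTYPE)
        self.params["b"] = np.zeros(n_classes, dtype=DTYPE)
        self._x: np.ndarray | None = None

    def forward(self, x, training=False, rng=None):
        b = x.shape[0]
        xf = x.reshape(b, -1)
        self._x = xf
        return xf @ self.params["w"].reshape(self.n_classes, -1).T + self.params["b"]

    def backward(self, dy):
        self.grads["w"] = (dy.T @ self._x).reshape(self.params["w"].shape)
        self.grads["b"] = dy.sum(axis=0)
        dx = dy @ self.params["w"].reshape(self.n_classes, -1)
        return dx.reshape(-1, self.f_s, self.l_in)


class LogSoftmax(Layer):
    def forward(self, x, training=False, rng=None):
        shifted = x - x.max(axis=1, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
        out = shifted - lse
        self._softmax = np.exp(out)
        return out

    def backward(self, dy):
        return dy - self._softmax * dy.sum(axis=1, keepdims=True)


class Adam:
    """Adam optimizer with per-parameter-group learning-rate factors and a
    coupled L2 penalty (gradient ``+= weight_decay * w``)."""

    def __init__(self, param_groups: list[dict], base_lr: float,
                 weight_decay: float = 0.0, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8) -> None:
        # each group: {"layers": [...], "lr_factor": float}
        self.groups = param_groups
        self.base_lr = float(base_lr)
        self.weight_decay = float(weight_decay)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.t = 0
        self.state: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for gi, group in enumerate(self.groups):
            lr = self.base_lr * group["lr_factor"]
            for li, layer in enumerate(group["layers"]):
                for name, w in layer.params.items():
                    g = layer.grads[name].astype(np.float64)
                    if self.weight_decay:
                        g = g + self.weight_decay * w
                    key = (gi, li, name)
                    if key not in self.state:
                        self.state[key] = (np.zeros_like(g), np.zeros_like(g))
                    m, v = self.state[key]
                    m *= self.b1
                    m += (1 - self.b1) * g
                    v *= self.b2
                    v += (1 - self.b2) * g * g
                    update = lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
                    w -= update.astype(w.dtype)
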