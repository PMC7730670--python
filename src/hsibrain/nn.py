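"""A compact, deterministic layer engine for the spectral-spatial networks.

Implements exactly what the classifiers in :mod:`hsibrain.models` need:
valid 3-D convolution, same-padded 2-D convolution, average pooling, dense
layers, ReLU, dropout, a merge of feature and spectral axes, softmax
cross-entropy and Adam.  Arrays are channels-last throughout:

* 3-D stage:  (N, H, W, D, C)  with D the spectral axis
* 2-D stage:  (N, H, W, C)

Convolutions are evaluated via ``sliding_window_view`` + one matmul per
layer (im2col), and gradients via the transposed scatter, so training speed
on small patch sets is dominated by BLAS.  All initialization randomness
comes from a caller-supplied ``numpy`` Generator, making runs bit-for-bit
reproducible for a fixed seed on a fixed BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ArchitectureError, ValidationError

#: Engine dtype: single precision keeps the BLAS-bound conv layers fast on CPU.
DTYPE = np.float32


class Layer:
    """Base layer: forward/backward plus (possibly empty) parameter lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    #: set by Network on its first parametric layer: dx there is never used
    skip_input_grad: bool = False

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def out_shape(self, in_shape: tuple) -> tuple:  # shape sans batch axis
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Conv3D(Layer):
    """Valid (unpadded) 3-D convolution over (H, W, D) with C input channels."""

    def __init__(self, in_ch: int, filters: int, kernel: tuple[int, int, int],
                 rng: np.random.Generator, layer_index: int = -1) -> None:
        super().__init__()
        self.kernel = tuple(int(k) for k in kernel)
        self.filters = int(filters)
        self.in_ch = int(in_ch)
        self.layer_index = layer_index
        kh, kw, kd = self.kernel
        fan_in = in_ch * kh * kw * kd
        self.W = _he_init(rng, (fan_in, filters), fan_in)
        self.b = np.zeros(filters, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def out_shape(self, in_shape):
        h, w, d, c = in_shape
        kh, kw, kd = self.kernel
        if kh > h or kw > w or kd > d:
            raise ArchitectureError(
                f"3-D conv layer {self.layer_index}: kernel {self.kernel} exceeds "
                f"remaining extent {(h, w, d)}"
            )
        return (h - kh + 1, w - kw + 1, d - kd + 1, self.filters)

    def forward(self, x, train):
        kh, kw, kd = self.kernel
        n, h, w, d, c = x.shape
        oh, ow, od, _ = self.out_shape(x.shape[1:])
        win = sliding_window_view(x, (kh, kw, kd), axis=(1, 2, 3))
        # win: (N, oh, ow, od, C, kh, kw, kd) -> cols (N*oh*ow*od, C*kh*kw*kd)
        cols = win.reshape(n * oh * ow * od, c * kh * kw * kd)
        self._cols, self._in_shape = cols, x.shape
        out = cols @ self.W + self.b
        return out.reshape(n, oh, ow, od, self.filters)

    def backward(self, grad):
        n, oh, ow, od, f = grad.shape
        g2 = grad.reshape(-1, f)
        self.grads[0][...] = self._cols.T @ g2
        self.grads[1][...] = g2.sum(axis=0)
        if self.skip_input_grad:
            return None
        kh, kw, kd = self.kernel
        _, h, w, d, c = self._in_shape
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        # scatter-add per kernel offset: one small matmul each keeps the
        # accumulated source contiguous (fast strided add)
        Wk = self.W.reshape(c, kh, kw, kd, f)
        for a in range(kh):
            for b_ in range(kw):
                for e in range(kd):
                    contrib = (g2 @ Wk[:, a, b_, e, :].T).reshape(n, oh, ow, od, c)
                    dx[:, a:a + oh, b_:b_ + ow, e:e + od, :] += contrib
        return dx


class MergeSpectral(Layer):
    """Reshape (N, H, W, D, C) -> (N, H, W, D*C): fold spectra into channels."""

    def out_shape(self, in_shape):
        h, w, d, c = in_shape
        return (h, w, d * c)

    def forward(self, x, train):
        self._shape = x.shape
        n, h, w, d, c = x.shape
        return x.reshape(n, h, w, d * c)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Conv2D(Layer):
    """Same-padded 2-D convolution (stride 1, odd kernels)."""

    def __init__(self, in_ch: int, filters: int, kernel: tuple[int, int],
                 rng: np.random.Generator, layer_index: int = -1) -> None:
        super().__init__()
        self.kernel = tuple(int(k) for k in kernel)
        if any(k % 2 == 0 for k in self.kernel):
            raise ArchitectureError(f"2-D conv layer {layer_index}: kernels must be odd")
        self.filters = int(filters)
        self.in_ch = int(in_ch)
        self.layer_index = layer_index
        kh, kw = self.kernel
        fan_in = in_ch * kh * kw
        self.W = _he_init(rng, (fan_in, filters), fan_in)
        self.b = np.zeros(filters, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def out_shape(self, in_shape):
        h, w, c = in_shape
        return (h, w, self.filters)

    def forward(self, x, train):
        kh, kw = self.kernel
        ph, pw = kh // 2, kw // 2
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        n, hp, wp, c = xp.shape
        oh, ow = hp - kh + 1, wp - kw + 1
        win = sliding_window_view(xp, (kh, kw), axis=(1, 2))
        cols = win.reshape(n * oh * ow, c * kh * kw)
        self._cols, self._xp_shape, self._pad = cols, xp.shape, (ph, pw)
        out = cols @ self.W + self.b
        return out.reshape(n, oh, ow, self.filters)

    def backward(self, grad):
        n, oh, ow, f = grad.shape
        g2 = grad.reshape(-1, f)
        self.grads[0][...] = self._cols.T @ g2
        self.grads[1][...] = g2.sum(axis=0)
        kh, kw = self.kernel
        ph, pw = self._pad
        _, hp, wp, c = self._xp_shape
        dxp = np.zeros(self._xp_shape, dtype=DTYPE)
        gW = (g2 @ self.W.T).reshape(n, oh, ow, c, kh, kw)
        for a in range(kh):
            for b_ in range(kw):
                dxp[:, a:a + oh, b_:b_ + ow, :] += gW[:, :, :, :, a, b_]
        return dxp[:, ph:hp - ph, pw:wp - pw, :]


class AvgPool2D(Layer):
    """2x2 stride-2 average pooling; odd trailing rows/cols are cropped."""

    def out_shape(self, in_shape):
        h, w, c = in_shape
        if h < 2 or w < 2:
            raise ArchitectureError("average pooling needs spatial extent >= 2")
        return (h // 2, w // 2, c)

    def forward(self, x, train):
        n, h, w, c = x.shape
        oh, ow = h // 2, w // 2
        self._in_shape = x.shape
        xc = x[:, : oh * 2, : ow * 2, :]
        return xc.reshape(n, oh, 2, ow, 2, c).mean(axis=(2, 4))

    def backward(self, grad):
        n, oh, ow, c = grad.shape
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        g = np.repeat(np.repeat(grad, 2, axis=1), 2, axis=2) / 4.0
        dx[:, : oh * 2, : ow * 2, :] = g
        return dx


class Flatten(Layer):
    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.W = _he_init(rng, (in_dim, out_dim), in_dim)
        self.b = np.zeros(out_dim, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def out_shape(self, in_shape):
        return (self.W.shape[1],)

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class ReLU(Layer):
    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; active only during training."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not (0 <= rate < 1):
            raise ValidationError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """A plain layer stack trained with Adam on softmax cross-entropy."""

    def __init__(self, layers: list[Layer], n_classes: int) -> None:
        self.layers = layers
        self.n_classes = n_classes
        self.loss_history: list[float] = []
        for layer in layers:  # the first parametric layer never needs dx
            if layer.params:
                layer.skip_input_grad = True
                break

    def forward(self, x: np.ndarray, train: bool = False, upto: int | None = None) -> np.ndarray:
        for layer in self.layers[:upto]:
            x = layer.forward(x, train)
        return x

    def predict_proba(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        out = [softmax(self.forward(x[i : i + batch])) for i in range(0, len(x), batch)]
        return np.concatenate(out) if out else np.zeros((0, self.n_classes))

    def fit(
        self,
        x: np.ndarray,
        y_onehot: np.ndarray,
        *,
        epochs: int,
        batch_size: int,
        lr: float,
        rng: np.random.Generator,
        class_weights: np.ndarray | None = None,
    ) -> list[float]:
        """Minimise (optionally class-weighted) cross-entropy; returns per-epoch loss."""
        params = [p for layer in self.layers for p in layer.params]
        grads = [g for layer in self.layers for g in layer.grads]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        n = len(x)
        self.loss_history = []
        for _ in range(epochs):
            order = rng.permutation(n)
            epoch_loss, seen = 0.0, 0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = x[idx], y_onehot[idx]
                logits = self.forward(xb, train=True)
                probs = softmax(logits)
                if class_weights is not None:
                    w = (yb * class_weights).sum(axis=1)
                else:
                    w = np.ones(len(xb))
                losses = -np.log(np.clip((probs * yb).sum(axis=1), 1e-12, None))
                epoch_loss += float((w * losses).sum())
                seen += float(w.sum())
                grad = (probs - yb) * w[:, None] / max(w.sum(), 1e-12)
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                t += 1
                a = lr * np.sqrt(1 - beta2**t) / (1 - beta1**t)
                for k, (p, g) in enumerate(zip(params, grads)):
                    m[k] = beta1 * m[k] + (1 - beta1) * g
                    v[k] = beta2 * v[k] + (1 - beta2) * g * g
                    p -= a * m[k] / (np.sqrt(v[k]) + eps)
            self.loss_history.append(epoch_loss / max(seen, 1))
        return self.loss_history
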