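"""Minimal CNN building blocks on numpy: forward, backprop, Adam.

Only what the two architectures in this study need: zero-padded same-size 2-D
convolutions, ReLU, 2x2 max-pooling, 2x nearest-neighbour up-sampling, block
average pooling, and a sequential container.  Layers cache what their
backward pass needs; all arithmetic is float32, all initialization flows
through an explicit ``numpy.random.Generator`` so that every build and every
training run is bit-reproducible from its seed.

Batches are ``(N, C, H, W)`` arrays.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "trainable", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.trainable = True
        self.name = name


class Layer:
    """Base class: stateless unless a subclass caches forward activations."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _pad_same(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))


class Conv2d(Layer):
    """k x k convolution, zero-padded to preserve H x W (odd k only).

    Kaiming fan-in initialization (suited to the ReLU nonlinearities used
    throughout), drawn from the supplied generator.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator, name: str = ""):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd to preserve spatial dims")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel))
        self.w = Param(w, name=f"{name}.w")
        self.b = Param(np.zeros(out_ch), name=f"{name}.b")
        #: first-layer convs set this False to skip the (large) input-grad pass
        self.needs_input_grad = True
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.in_ch:
            raise ValueError(
                f"expected (N, {self.in_ch}, H, W) input, got {x.shape}"
            )
        self._x = x
        pad = self.kernel // 2
        xp = _pad_same(x, pad)
        cols = sliding_window_view(xp, (self.kernel, self.kernel), axis=(2, 3))
        # (N,C,H,W,k,k) . (O,C,k,k) -> (N,H,W,O)
        out = np.tensordot(cols, self.w.value, axes=([1, 4, 5], [1, 2, 3]))
        out += self.b.value
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2), dtype=np.float32)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x, k = self._x, self.kernel
        pad = k // 2
        xp = _pad_same(x, pad)
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))
        self.b.grad += grad_out.sum(axis=(0, 2, 3))
        # (N,O,H,W) . (N,C,H,W,k,k) over N,H,W -> (O,C,k,k)
        self.w.grad += np.tensordot(grad_out, cols, axes=([0, 2, 3], [0, 2, 3]))
        if not self.needs_input_grad:
            return None
        gp = _pad_same(grad_out, pad)
        gcols = sliding_window_view(gp, (k, k), axis=(2, 3))
        w_flip = self.w.value[:, :, ::-1, ::-1]
        grad_x = np.tensordot(gcols, w_flip, axes=([1, 4, 5], [0, 2, 3]))
        return np.ascontiguousarray(grad_x.transpose(0, 3, 1, 2), dtype=np.float32)


class ReLU(Layer):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(np.float32)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad_out, 0).astype(np.float32)


class MaxPool2(Layer):
    """2x2 max-pooling, stride 2; ties route to the first element."""

    def __init__(self):
        self._idx: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max-pool needs even spatial dims, got {h}x{w}")
        self._shape = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]
        return np.ascontiguousarray(out)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        g = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(g, self._idx[..., None], grad_out[..., None], axis=-1)
        g = g.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(g.reshape(n, c, h, w))


class UpsampleNearest2(Layer):
    """2x nearest-neighbour up-sampling; backward sums each 2x2 block."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c, h, w = grad_out.shape
        g = grad_out.reshape(n, c, h // 2, 2, w // 2, 2)
        return np.ascontiguousarray(g.sum(axis=(3, 5)), dtype=np.float32)


class UpsampleBilinear2(Layer):
    """2x bilinear up-sampling (align_corners=False convention)."""

    def __init__(self):
        self._in_shape: tuple | None = None
        self._wmat_h: np.ndarray | None = None
        self._wmat_w: np.ndarray | None = None

    def _weights(self, n_in: int) -> np.ndarray:
        n_out = 2 * n_in
        # output sample i maps to input coordinate (i + 0.5)/2 - 0.5
        src = (np.arange(n_out) + 0.5) / 2.0 - 0.5
        lo = np.clip(np.floor(src).astype(int), 0, n_in - 1)
        hi = np.clip(lo + 1, 0, n_in - 1)
        frac = np.clip(src - lo, 0.0, 1.0)
        m = np.zeros((n_out, n_in), dtype=np.float32)
        m[np.arange(n_out), lo] += 1 - frac
        m[np.arange(n_out), hi] += frac
        return m

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if self._in_shape != x.shape:
            self._in_shape = x.shape
            self._wmat_h = self._weights(h)
            self._wmat_w = self._weights(w)
        out = np.einsum("oh,nchw->ncow", self._wmat_h, x)
        return np.einsum("pw,ncow->ncop", self._wmat_w, out).astype(np.float32)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = np.einsum("pw,ncop->ncow", self._wmat_w, grad_out)
        return np.einsum("oh,ncow->nchw", self._wmat_h, g).astype(np.float32)


class AvgPool(Layer):
    """Non-overlapping block average pooling by an integer factor."""

    def __init__(self, factor: int):
        self.factor = factor
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        f = self.factor
        if h % f or w % f:
            raise ValueError(f"spatial dims must divide by {f}, got {h}x{w}")
        self._shape = x.shape
        return x.reshape(n, c, h // f, f, w // f, f).mean(axis=(3, 5), dtype=np.float32)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        f = self.factor
        g = np.repeat(np.repeat(grad_out, f, axis=2), f, axis=3) / (f * f)
        return g.astype(np.float32)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
            if grad_out is None:  # a first-layer conv opted out of input grads
                break
        return grad_out


class Adam:
    """Adam with the standard bias-corrected moment estimates.

    ``lr`` is mutable so a plateau scheduler can rescale it mid-run; frozen
    parameters (``trainable=False``) are skipped entirely.
    """

    def __init__(self, params: list[Param], lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if not p.trainable:
                continue
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
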