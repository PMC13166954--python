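"""Layers, a record-replay tape, and SGD.

Every layer implements ``forward(*arrays) -> array`` and
``backward(grad_out) -> tuple(grad_inputs)``; parameter gradients
accumulate on the layer's :class:`Param` objects.  A layer instance may
appear at most once per forward pass (its caches are overwritten on each
call), which holds for the feed-forward detection graphs built here.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def to_cnhw(batch_nhwc: np.ndarray) -> np.ndarray:
    """(N, H, W, C) image batch -> (C, N, H, W) float32 activations."""
    return np.ascontiguousarray(batch_nhwc.transpose(3, 0, 1, 2), dtype=DTYPE)


def from_cnhw(act: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(act.transpose(1, 2, 3, 0))


class Param:
    __slots__ = ("data", "grad", "name", "lr_scale")

    def __init__(self, data: np.ndarray, name: str = "",
                 lr_scale: float = 1.0):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)
        self.name = name
        self.lr_scale = lr_scale  # per-parameter learning-rate multiplier


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, *xs: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, ...]:  # pragma: no cover
        raise NotImplementedError


class Var:
    __slots__ = ("data", "vid")

    def __init__(self, data: np.ndarray, vid: int):
        self.data = data
        self.vid = vid


class Tape:
    """Records layer applications; replays them in reverse for gradients."""

    def __init__(self):
        self._records: list[tuple[Layer, tuple[int, ...], int]] = []
        self._next = 0

    def leaf(self, data: np.ndarray) -> Var:
        v = Var(data, self._next)
        self._next += 1
        return v

    def apply(self, layer: Layer, *xs: Var) -> Var:
        y = layer.forward(*(x.data for x in xs))
        out = Var(y, self._next)
        self._next += 1
        self._records.append((layer, tuple(x.vid for x in xs), out.vid))
        return out

    def backward(self, seeds: dict[int, np.ndarray]) -> dict[int, np.ndarray]:
        """Propagate output-variable gradients back to every variable."""
        grads: dict[int, np.ndarray] = {k: np.asarray(v, dtype=DTYPE)
                                        for k, v in seeds.items()}
        for layer, in_ids, out_id in reversed(self._records):
            dy = grads.pop(out_id, None)
            if dy is None:
                continue
            dxs = layer.backward(dy)
            for vid, dx in zip(in_ids, dxs):
                if dx is None:
                    continue
                if vid in grads:
                    grads[vid] += dx
                else:
                    grads[vid] = dx
        return grads


# ---------------------------------------------------------------------------
# Convolution (im2col + GEMM, channel-first layout)
# ---------------------------------------------------------------------------

def _im2col(xpad: np.ndarray, kh: int, kw: int, stride: int,
            ho: int, wo: int) -> np.ndarray:
    """(C, N, Hp, Wp) -> (C*kh*kw, N*ho*wo) patch matrix."""
    c, n = xpad.shape[:2]
    cols = np.empty((c, kh, kw, n * ho * wo), dtype=DTYPE)
    for i in range(kh):
        for j in range(kw):
            view = xpad[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
            cols[:, i, j] = view.reshape(c, -1)
    return cols.reshape(c * kh * kw, -1)


def _col2im(dcols: np.ndarray, shape, kh: int, kw: int, stride: int,
            ho: int, wo: int) -> np.ndarray:
    c, n, hp, wp = shape
    dxpad = np.zeros(shape, dtype=DTYPE)
    dv = dcols.reshape(c, kh, kw, n, ho, wo)
    for i in range(kh):
        for j in range(kw):
            dxpad[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += dv[:, i, j]
    return dxpad


class Conv2d(Layer):
    """2-D convolution with odd kernel, 'same'-style padding k//2."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 zero_init: bool = False, needs_input_grad: bool = True,
                 name: str = ""):
        if k % 2 == 0:
            raise ValueError("kernel must be odd-sized")
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.needs_input_grad = needs_input_grad
        self.pad = k // 2
        if zero_init:
            w = np.zeros((c_out, c_in, k, k))
        else:
            rng = rng or np.random.default_rng(0)
            # He-style fan-in scaling
            w = rng.normal(0.0, np.sqrt(2.0 / (c_in * k * k)),
                           size=(c_out, c_in, k, k))
        self.weight = Param(w, name + ".weight")
        self.bias = Param(np.zeros(c_out), name + ".bias") if bias else None
        self._cache = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        return ((h + 2 * self.pad - self.k) // self.stride + 1,
                (w + 2 * self.pad - self.k) // self.stride + 1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, n, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        ho, wo = self.out_hw(h, w)
        p = self.pad
        if self.k == 1 and self.stride == 1:
            cols = np.ascontiguousarray(x, dtype=DTYPE).reshape(c, -1)
            xpad_shape = x.shape
        else:
            if p:
                xpad = np.zeros((c, n, h + 2 * p, w + 2 * p), dtype=DTYPE)
                xpad[:, :, p:p + h, p:p + w] = x
            else:
                xpad = np.asarray(x, dtype=DTYPE)
            cols = _im2col(xpad, self.k, self.k, self.stride, ho, wo)
            xpad_shape = xpad.shape
        w2d = self.weight.data.reshape(self.c_out, -1)
        y = w2d @ cols
        if self.bias is not None:
            y += self.bias.data[:, None]
        self._cache = (cols, xpad_shape, (h, w), (ho, wo), n)
        return y.reshape(self.c_out, n, ho, wo)

    def backward(self, dy: np.ndarray):
        cols, pad_shape, (h, w), (ho, wo), n = self._cache
        dyf = np.ascontiguousarray(dy, dtype=DTYPE).reshape(self.c_out, -1)
        self.weight.grad += (dyf @ cols.T).reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += dyf.sum(axis=1)
        self._cache = None
        if not self.needs_input_grad:
            return (None,)
        dcols = self.weight.data.reshape(self.c_out, -1).T @ dyf
        if self.k == 1 and self.stride == 1:
            return (dcols.reshape(pad_shape),)
        dxpad = _col2im(dcols, pad_shape, self.k, self.k, self.stride, ho, wo)
        p = self.pad
        dx = dxpad[:, :, p:p + h, p:p + w] if p else dxpad
        return (np.ascontiguousarray(dx),)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = ""):
        self.c, self.momentum, self.eps = c, momentum, eps
        self.gamma = Param(np.ones(c), name + ".gamma")
        self.beta = Param(np.zeros(c), name + ".beta")
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.training = True
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c = x.shape[0]
        xf = x.reshape(c, -1)
        m = xf.shape[1]
        if self.training:
            mean = xf.sum(axis=1) / m
            # E[x^2] - E[x]^2 in one pass; clip tiny negatives from cancellation
            var = np.maximum(np.einsum("ij,ij->i", xf, xf) / m - mean * mean, 0.0)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        a = self.gamma.data * invstd
        b = self.beta.data - a * mean.astype(DTYPE)
        y = x * a[:, None, None, None]
        y += b[:, None, None, None]
        self._cache = (x, mean.astype(DTYPE), invstd)
        return y

    def backward(self, dy: np.ndarray):
        x, mean, invstd = self._cache
        c = dy.shape[0]
        dyf = dy.reshape(c, -1)
        xf = x.reshape(c, -1)
        m = dyf.shape[1]
        dbeta = dyf.sum(axis=1)
        # sum(dy * xhat) = invstd * (sum(dy*x) - mean*sum(dy))
        dgamma = invstd * (np.einsum("ij,ij->i", dyf, xf) - mean * dbeta)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.data * invstd
        if self.training:
            # dx = g * (dy - dbeta/m - xhat * dgamma/m),  xhat = (x - mean)*invstd
            c1 = g[:, None, None, None]
            k = (dgamma / m) * invstd
            dx = dy - (dbeta / m - mean * k)[:, None, None, None]
            dx -= x * k[:, None, None, None]
            dx *= c1
        else:
            dx = dy * g[:, None, None, None]
        self._cache = None
        return (dx.astype(DTYPE, copy=False),)


class SiLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        sig = np.empty_like(x)
        np.negative(x, out=sig)
        np.exp(sig, out=sig)
        sig += 1.0
        np.reciprocal(sig, out=sig)
        self._cache = (x, sig)
        return x * sig

    def backward(self, dy: np.ndarray):
        x, sig = self._cache
        self._cache = None
        # d/dx x*sig(x) = sig * (1 + x * (1 - sig))
        d = 1.0 - sig
        d *= x
        d += 1.0
        d *= sig
        d *= dy
        return (d,)


class UpsampleNearest2x(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray):
        c, n, h2, w2 = dy.shape
        dx = dy.reshape(c, n, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
        return (np.ascontiguousarray(dx, dtype=DTYPE),)


class Concat(Layer):
    """Channel-axis concatenation of a fixed number of inputs."""

    def forward(self, *xs: np.ndarray) -> np.ndarray:
        self._sizes = [x.shape[0] for x in xs]
        return np.concatenate(xs, axis=0)

    def backward(self, dy: np.ndarray):
        out, start = [], 0
        for s in self._sizes:
            out.append(np.ascontiguousarray(dy[start:start + s]))
            start += s
        return tuple(out)


class SGD:
    """SGD with classical momentum and optional cosine learning-rate decay."""

    def __init__(self, params: list[Param], lr: float = 0.01,
                 momentum: float = 0.937, weight_decay: float = 0.0):
        self.params = params
        self.lr0 = self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.data) for p in params]

    def set_cosine_lr(self, step: int, total_steps: int, final_fraction: float = 0.05):
        frac = final_fraction + 0.5 * (1 - final_fraction) * (
            1 + np.cos(np.pi * min(step, total_steps) / max(1, total_steps)))
        self.lr = self.lr0 * frac

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        for p, v in zip(self.params, self._vel):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * p.lr_scale * v
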