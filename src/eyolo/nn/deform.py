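"""Deformable convolution with learned per-location sampling offsets.

The operator computes, at each output coordinate xi_0,

    f(xi_0) = sum_{xi in S} omega(xi) * g(xi_0 + xi + Delta_xi)

where S is the base kernel grid, omega the kernel weights and Delta_xi a
learned 2-D displacement per output location and base offset.  Fractional
sampling positions are evaluated by bilinear interpolation; positions
outside the feature map contribute zero.  The offsets are predicted by a
parallel plain 3x3 convolution over the same input whose weights are
zero-initialized, so an untrained layer reduces exactly to a standard
convolution.

Implementation note: sampling and its adjoint work in a pixel-major
(N*H*W, C) layout -- bilinear gathers become contiguous row copies and
the input-gradient scatter becomes a single sparse matrix product --
which keeps the cost of the deformable blocks small next to the GEMMs.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from eyolo.nn.core import DTYPE, Conv2d, Layer, Param

# corner order: (dy, dx) in {0,1}^2
_CORNERS = ((0, 0), (0, 1), (1, 0), (1, 1))


class DeformConv2d(Layer):
    """Odd-kernel deformable convolution, stride 1, 'same' padding."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, bias: bool = True,
                 rng: np.random.Generator | None = None, name: str = ""):
        if k % 2 == 0:
            raise ValueError("kernel must be odd-sized")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad = k // 2
        rng = rng or np.random.default_rng(0)
        self.weight = Param(
            rng.normal(0.0, np.sqrt(2.0 / (c_in * k * k)), (c_out, c_in, k, k)),
            name + ".weight")
        self.bias = Param(np.zeros(c_out), name + ".bias") if bias else None
        # offset branch: 2 channels (dy, dx) per base offset, zero-initialized
        self.offset_conv = Conv2d(c_in, 2 * k * k, 3, stride=1, bias=True,
                                  zero_init=True, name=name + ".offset")
        # offsets learn at a reduced rate: the sampling geometry drifting
        # faster than the features it samples destabilizes early training
        for p in self.offset_conv.params():
            p.lr_scale = 0.1
        self.last_offsets: np.ndarray | None = None
        self.pending_offset_grad: np.ndarray | None = None
        self._cache = None

    def params(self):
        ps = [self.weight] + ([self.bias] if self.bias is not None else [])
        return ps + self.offset_conv.params()

    def _sample_geometry(self, offsets, n, h, w):
        """Corner indices/weights for every base offset.

        Returns per-tap tuples (idx4 (P,4) int64 into the flat (N*H*W) map,
        w4 (P,4) effective bilinear weights, frac (P,2) = (wy, wx),
        valid4 (P,4)).
        """
        p_all = n * h * w
        gy = np.arange(h, dtype=DTYPE)[None, :, None]
        gx = np.arange(w, dtype=DTYPE)[None, None, :]
        nbase = (np.arange(n, dtype=np.int64) * (h * w))[:, None, None]
        geom = []
        for t in range(self.k * self.k):
            i, j = divmod(t, self.k)
            py = (gy + (i - self.pad) + offsets[2 * t]).reshape(-1)
            px = (gx + (j - self.pad) + offsets[2 * t + 1]).reshape(-1)
            y0 = np.floor(py).astype(np.int64)
            x0 = np.floor(px).astype(np.int64)
            wy = (py - y0).astype(DTYPE)
            wx = (px - x0).astype(DTYPE)
            idx4 = np.empty((p_all, 4), dtype=np.int64)
            w4 = np.empty((p_all, 4), dtype=DTYPE)
            valid4 = np.empty((p_all, 4), dtype=bool)
            wcs = ((1 - wy) * (1 - wx), (1 - wy) * wx, wy * (1 - wx), wy * wx)
            nflat = nbase.reshape(n, 1, 1).repeat(h, 1).repeat(w, 2).reshape(-1)
            for ci, (dy_c, dx_c) in enumerate(_CORNERS):
                yc, xc = y0 + dy_c, x0 + dx_c
                valid = (yc >= 0) & (yc < h) & (xc >= 0) & (xc < w)
                idx4[:, ci] = np.clip(yc, 0, h - 1) * w + np.clip(xc, 0, w - 1) \
                    + nflat
                w4[:, ci] = wcs[ci] * valid
                valid4[:, ci] = valid
            geom.append((idx4, w4, np.stack([wy, wx], axis=1), valid4))
        return geom

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, n, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        offsets = self.offset_conv.forward(x)  # (2k^2, N, H, W)
        self.last_offsets = offsets
        kk = self.k * self.k
        p_all = n * h * w
        x_t = np.ascontiguousarray(x.reshape(c, p_all).T)  # (P, C)
        geom = self._sample_geometry(offsets, n, h, w)
        # one sparse gather covers every tap and corner at once
        rows = np.repeat(np.arange(kk * p_all, dtype=np.int64), 4)
        cols_idx = np.concatenate([g[0].reshape(-1) for g in geom])
        data = np.concatenate([g[1].reshape(-1) for g in geom])
        gather = sparse.csr_matrix((data, (rows, cols_idx)),
                                   shape=(kk * p_all, p_all))
        cols_t = (gather @ x_t).reshape(kk, p_all, c)
        y_t = np.zeros((p_all, self.c_out), dtype=DTYPE)
        wmat = self.weight.data.reshape(self.c_out, c, kk)
        for t in range(kk):
            y_t += cols_t[t] @ wmat[:, :, t].T
        if self.bias is not None:
            y_t += self.bias.data
        self._cache = (x_t, offsets, cols_t, geom, gather, (n, h, w))
        return np.ascontiguousarray(y_t.T).reshape(self.c_out, n, h, w)

    def backward(self, dy: np.ndarray):
        x_t, offsets, cols_t, geom, gather, (n, h, w) = self._cache
        c, kk = self.c_in, self.k * self.k
        p_all = n * h * w
        dy_t = np.ascontiguousarray(
            dy.reshape(self.c_out, p_all).T.astype(DTYPE, copy=False))
        if self.bias is not None:
            self.bias.grad += dy_t.sum(axis=0)
        wmat = self.weight.data.reshape(self.c_out, c, kk)
        dwmat = np.empty((self.c_out, c, kk), dtype=DTYPE)
        dcols_t = np.empty((kk, p_all, c), dtype=DTYPE)
        doff = np.empty_like(offsets)
        for t, (idx4, w4, frac, valid4) in enumerate(geom):
            dwmat[:, :, t] = dy_t.T @ cols_t[t]
            dg = dy_t @ wmat[:, :, t]  # (P, C)
            dcols_t[t] = dg
            # offset gradient via d(bilinear weight)/d(py, px)
            wy, wx = frac[:, 0], frac[:, 1]
            dpy = np.zeros(p_all, dtype=DTYPE)
            dpx = np.zeros(p_all, dtype=DTYPE)
            dw_dy = (-(1 - wx), -wx, (1 - wx), wx)
            dw_dx = (-(1 - wy), (1 - wy), -wy, wy)
            for ci in range(4):
                vals = np.einsum("pc,pc->p", x_t[idx4[:, ci]], dg)
                vm = valid4[:, ci]
                dpy += vals * dw_dy[ci] * vm
                dpx += vals * dw_dx[ci] * vm
            doff[2 * t] = dpy.reshape(n, h, w)
            doff[2 * t + 1] = dpx.reshape(n, h, w)
        self.weight.grad += dwmat.reshape(self.weight.data.shape)

        # input gradient: adjoint of the forward sparse gather
        dx_t = gather.T @ dcols_t.reshape(kk * p_all, c)

        if self.pending_offset_grad is not None:
            doff += self.pending_offset_grad
            self.pending_offset_grad = None
        (dx_off,) = self.offset_conv.backward(doff)
        self._cache = None
        dx = np.ascontiguousarray(dx_t.T).reshape(c, n, h, w) + dx_off
        return (dx,)
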