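"""Minimal CNN building blocks with explicit backprop (numpy only).

Tensors are channels-first ``(C, *spatial)`` with 2 or 3 spatial
dimensions.  Each layer caches what it needs in ``forward`` and returns
input gradients from ``backward``; parameter gradients accumulate in
``.grads`` aligned with ``.params``.  Convolutions are stride-1
zero-padded 'same' via im2col; pooling and up-convolution use factor-2
blocks, so spatial dims entering them must be even (the model reflect-
pads beforehand).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv", "ReLU", "MaxPool", "UpConv", "Sequential"]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(C, *S) -> (prod(S), C*k^d) patch matrix with zero 'same' pad."""
    nd = x.ndim - 1
    p = k // 2
    xp = np.pad(x, ((0, 0),) + ((p, p),) * nd)
    win = sliding_window_view(xp, (k,) * nd, axis=tuple(range(1, nd + 1)))
    # win: (C, *S, k..k) -> (*S, C, k..k)
    perm = tuple(range(1, nd + 1)) + (0,) + tuple(range(nd + 1, 2 * nd + 1))
    cols = win.transpose(perm)
    n_sp = int(np.prod(x.shape[1:]))
    return np.ascontiguousarray(cols).reshape(n_sp, x.shape[0] * k**nd)


class Conv:
    """Stride-1 'same' convolution, kernel edge ``k`` (3 or 1)."""

    def __init__(self, cin: int, cout: int, ndim: int, k: int = 3, rng=None):
        rng = rng or np.random.default_rng()
        fan_in = cin * k**ndim
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin) + (k,) * ndim)
        b = np.zeros(cout)
        self.k, self.ndim = k, ndim
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        w, b = self.params
        self._sp = x.shape[1:]
        self._cols = _im2col(x, self.k)
        wmat = w.reshape(w.shape[0], -1)
        y = (self._cols @ wmat.T).T.reshape((w.shape[0],) + self._sp)
        return y + b.reshape((-1,) + (1,) * self.ndim)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w, _ = self.params
        cout = w.shape[0]
        dyf = dy.reshape(cout, -1)
        self.grads[0] += (dyf @ self._cols).reshape(w.shape)
        self.grads[1] += dyf.sum(axis=1)
        # input grad = 'same' conv of dy with channel-swapped, flipped kernel
        wt = np.flip(w, axis=tuple(range(2, 2 + self.ndim))).swapaxes(0, 1)
        cols = _im2col(dy, self.k)
        wmat = np.ascontiguousarray(wt).reshape(wt.shape[0], -1)
        return (cols @ wmat.T).T.reshape((wt.shape[0],) + self._sp)


class ReLU:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class MaxPool:
    """Factor-2 max pooling over every spatial axis."""

    params: list = []
    grads: list = []

    def __init__(self, ndim: int):
        self.ndim = ndim

    def _block_view(self, x):
        c = x.shape[0]
        sp = x.shape[1:]
        half = tuple(s // 2 for s in sp)
        shape = (c,) + sum(((h, 2) for h in half), ())
        xb = x.reshape(shape)
        perm = (0,) + tuple(1 + 2 * a for a in range(self.ndim)) + tuple(
            2 + 2 * a for a in range(self.ndim)
        )
        return np.ascontiguousarray(xb.transpose(perm)).reshape(
            (c,) + half + (2**self.ndim,)
        ), half

    def forward(self, x: np.ndarray) -> np.ndarray:
        if any(s % 2 for s in x.shape[1:]):
            raise ValueError(f"pooling needs even spatial dims, got {x.shape[1:]}")
        blocks, half = self._block_view(x)
        self._idx = np.argmax(blocks, axis=-1)
        self._half = half
        self._in_shape = x.shape
        return np.take_along_axis(blocks, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c = self._in_shape[0]
        blocks = np.zeros((c,) + self._half + (2**self.ndim,))
        np.put_along_axis(blocks, self._idx[..., None], dy[..., None], axis=-1)
        # undo the transpose/reshape of _block_view
        inter = blocks.reshape((c,) + self._half + (2,) * self.ndim)
        perm = [0]
        for a in range(self.ndim):
            perm.extend([1 + a, 1 + self.ndim + a])
        return np.ascontiguousarray(inter.transpose(perm)).reshape(self._in_shape)


class UpConv:
    """Transposed convolution, kernel 2, stride 2 (exact doubling)."""

    def __init__(self, cin: int, cout: int, ndim: int, rng=None):
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / cin), size=(cin, cout) + (2,) * ndim)
        b = np.zeros(cout)
        self.ndim = ndim
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        w, b = self.params
        self._x = x
        if self.ndim == 2:
            y = np.einsum("cij,cdpq->dipjq", x, w)
        else:
            y = np.einsum("cijk,cdpqr->dipjqkr", x, w)
        sp = tuple(2 * s for s in x.shape[1:])
        return y.reshape((w.shape[1],) + sp) + b.reshape((-1,) + (1,) * self.ndim)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w, _ = self.params
        x = self._x
        half = x.shape[1:]
        if self.ndim == 2:
            blocks = dy.reshape(dy.shape[0], half[0], 2, half[1], 2)
            self.grads[0] += np.einsum("cij,dipjq->cdpq", x, blocks)
            dx = np.einsum("dipjq,cdpq->cij", blocks, w)
        else:
            blocks = dy.reshape(dy.shape[0], half[0], 2, half[1], 2, half[2], 2)
            self.grads[0] += np.einsum("cijk,dipjqkr->cdpqr", x, blocks)
            dx = np.einsum("dipjqkr,cdpqr->cijk", blocks, w)
        self.grads[1] += dy.reshape(dy.shape[0], -1).sum(axis=1)
        return dx


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy
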