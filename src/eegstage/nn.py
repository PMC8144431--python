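"""Minimal 3D-convolution network engine in numpy.

Implements exactly the pieces the multi-branch 3D CNN needs: valid (unpadded)
strided 3D convolution with explicit backward passes, ReLU, dense layers,
inverted dropout, Glorot ("normalized") uniform initialization and the Adam
optimizer.  Activations are channels-last (N, H, W, T, C); convolutions are
lowered to matrix multiplications via sliding window views so the heavy
lifting runs in BLAS, and gradients w.r.t. inputs are scattered back with one
strided slice-add per kernel offset.

Everything is deterministic given the numpy Generators passed in; default
parameter dtype is float32 (float64 is used by the gradient-check tests).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

DEFAULT_DTYPE = np.float32


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int,
                   dtype=DEFAULT_DTYPE) -> np.ndarray:
    """Normalized initialization: U(+-sqrt(6 / (fan_in + fan_out)))."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def conv_output_extent(in_extent: int, kernel: int, stride: int) -> int:
    """Valid-convolution output length: floor((in - kernel) / stride) + 1."""
    if kernel > in_extent:
        return 0
    return (in_extent - kernel) // stride + 1


class Layer:
    """Forward/backward building block with optional parameters."""

    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, training: bool,
                rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def im2col(x: np.ndarray, kernel, stride) -> np.ndarray:
    """Lower sliding 3D patches of a channels-last batch to a matrix.

    Returns shape ``(n * oh * ow * ot, kh * kw * kt * c)``; each row is one
    kernel placement with the channel block innermost.
    """
    kh, kw, kt = kernel
    sh, sw, st = stride
    view = np.lib.stride_tricks.sliding_window_view(
        x, (kh, kw, kt), axis=(1, 2, 3))[:, ::sh, ::sw, ::st]
    n, oh, ow, ot = view.shape[:4]
    cols = np.ascontiguousarray(view.transpose(0, 1, 2, 3, 5, 6, 7, 4))
    return cols.reshape(n * oh * ow * ot, kh * kw * kt * x.shape[4])


class Conv3D(Layer):
    """Valid strided 3D convolution over channels-last (N, H, W, T, C) inputs.

    Channels-last keeps each patch's channel block contiguous, so the
    im2col gather moves whole cache lines and the matmul output is already
    in the layout the next layer consumes.
    """

    def __init__(self, c_in: int, c_out: int, kernel, stride,
                 rng: np.random.Generator, dtype=DEFAULT_DTYPE):
        kh, kw, kt = kernel
        k = kh * kw * kt
        self.kernel = tuple(int(v) for v in kernel)
        self.stride = tuple(int(v) for v in stride)
        # stored (kh, kw, kt, c_in, c_out) to match the patch layout
        self.W = glorot_uniform(rng, (kh, kw, kt, c_in, c_out),
                                fan_in=c_in * k, fan_out=c_out * k, dtype=dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._cache = None

    def out_extents(self, in_shape) -> tuple[int, int, int]:
        return tuple(conv_output_extent(e, k, s) for e, k, s
                     in zip(in_shape, self.kernel, self.stride))

    def forward(self, x, training, rng=None, cols=None, need_dx=True):
        """``cols`` lets callers share one im2col across layers with equal
        kernel/stride on the same input; ``need_dx=False`` (first layers)
        skips the input-gradient scatter in backward."""
        if cols is None:
            cols = im2col(x, self.kernel, self.stride)
        n = x.shape[0]
        oh, ow, ot = self.out_extents(x.shape[1:4])
        f = self.W.shape[-1]
        out = cols @ self.W.reshape(-1, f) + self.b
        self._cache = (x.shape, cols, (n, oh, ow, ot), need_dx)
        return out.reshape(n, oh, ow, ot, f)

    def backward(self, dout):
        x_shape, cols, (n, oh, ow, ot), need_dx = self._cache
        f = self.W.shape[-1]
        c = x_shape[4]
        kh, kw, kt = self.kernel
        sh, sw, st = self.stride
        dmat = dout.reshape(-1, f)
        self.grads[0][...] = (cols.T @ dmat).reshape(self.W.shape)
        self.grads[1][...] = dmat.sum(axis=0)
        if not need_dx:
            return None
        dcols = (dmat @ self.W.reshape(-1, f).T).reshape(
            n, oh, ow, ot, kh, kw, kt, c)
        dx = np.zeros(x_shape, dtype=dout.dtype)
        for i in range(kh):
            for j in range(kw):
                for k in range(kt):
                    dx[:, i:i + sh * oh:sh, j:j + sw * ow:sw,
                       k:k + st * ot:st, :] += dcols[:, :, :, :, i, j, k, :]
        return dx


class ReLU(Layer):
    def forward(self, x, training, rng=None):
        self._mask = x > 0
        np.maximum(x, 0, out=x)  # x is always a fresh buffer here
        return x

    def backward(self, dout):
        dout *= self._mask
        return dout


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=DEFAULT_DTYPE):
        self.W = glorot_uniform(rng, (n_in, n_out), n_in, n_out, dtype=dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float):
        if not 0 <= p < 1:
            raise ValueError("dropout fraction must lie in [0, 1)")
        self.p = p

    def forward(self, x, training, rng=None):
        if not training or self.p == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask.astype(x.dtype)

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask.astype(dout.dtype)


class MultiBranchNet:
    """Parallel conv branches -> flatten + concatenate -> dense head."""

    def __init__(self, branches: Sequence[Sequence[Layer]],
                 head: Sequence[Layer]):
        self.branches = [list(b) for b in branches]
        self.head = list(head)
        self._branch_shapes: list[tuple] | None = None

    # -- parameter plumbing -------------------------------------------------

    def layers(self) -> list[Layer]:
        out: list[Layer] = []
        for b in self.branches:
            out.extend(b)
        out.extend(self.head)
        return out

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers() for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers() for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(weights):
            raise ValueError("weight list length mismatch")
        for p, w in zip(params, weights):
            p[...] = w

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        # branches with identical first-layer geometry share one im2col
        shared: dict[tuple, np.ndarray] = {}
        feats = []
        shapes = []
        for branch in self.branches:
            h = x
            for li, layer in enumerate(branch):
                if li == 0 and isinstance(layer, Conv3D):
                    key = (layer.kernel, layer.stride)
                    if key not in shared:
                        shared[key] = im2col(x, layer.kernel, layer.stride)
                    h = layer.forward(h, training, rng, cols=shared[key],
                                      need_dx=False)
                else:
                    h = layer.forward(h, training, rng)
            shapes.append(h.shape)
            feats.append(h.reshape(h.shape[0], -1))
        self._branch_shapes = shapes
        h = np.concatenate(feats, axis=1)
        for layer in self.head:
            h = layer.forward(h, training, rng)
        return h

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.head):
            d = layer.backward(d)
        offset = 0
        for branch, shape in zip(self.branches, self._branch_shapes):
            size = int(np.prod(shape[1:]))
            db = d[:, offset:offset + size].reshape(shape)
            offset += size
            for layer in reversed(branch):
                db = layer.backward(db)


class Adam:
    """Adam with the customary defaults (b1=0.9, b2=0.999, eps=1e-8)."""

    def __init__(self, params: Sequence[np.ndarray], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= (self.lr * (m / bias1)
                  / (np.sqrt(v / bias2) + self.eps)).astype(p.dtype)
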