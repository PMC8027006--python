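"""A compact reverse-mode automatic-differentiation engine on numpy arrays.

Provides exactly the primitives the landmark network needs: broadcasting
arithmetic, matmul, ReLU, 2-D convolution (im2col), batch normalisation,
nearest-neighbour upsampling, concatenation, a spatial softmax, and reduction
ops.  Gradients are accumulated by a topological backward sweep; every fused
primitive carries a hand-written backward verified against finite
differences in the test suite.

This is deliberately minimal: float64 throughout, no graphs across calls, no
in-place ops.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph mechanics ----------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=float)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        out._backward = bwd
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            self._accum(g @ np.swapaxes(other.data, -1, -2))
            other._accum(np.swapaxes(self.data, -1, -2) @ g)

        out._backward = bwd
        return out

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        orig = self.shape
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, axes)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities ------------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# fused network primitives (NCHW layout)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) via im2col + matmul."""
    b, cin, h, w = x.shape
    cout, cin_w, kh, kw = weight.shape
    assert cin == cin_w, f"channel mismatch {cin} vs {cin_w}"
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hout = (h + 2 * pad - kh) // stride + 1
    wout = (w + 2 * pad - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (B, Cin, Hout, Wout, kh, kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, hout, wout, cin * kh * kw)
    wmat = weight.data.reshape(cout, cin * kh * kw)
    out_data = cols @ wmat.T  # (B, Hout, Wout, Cout)
    if bias is not None:
        out_data = out_data + bias.data
    out_data = out_data.transpose(0, 3, 1, 2)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(np.ascontiguousarray(out_data), parents=parents)

    def bwd(g):
        gmat = g.transpose(0, 2, 3, 1)  # (B, Hout, Wout, Cout)
        weight._accum(
            np.tensordot(gmat, cols, axes=([0, 1, 2], [0, 1, 2])).reshape(weight.shape)
        )
        if bias is not None:
            bias._accum(gmat.sum(axis=(0, 1, 2)))
        dcols = gmat @ wmat  # (B, Hout, Wout, Cin*kh*kw)
        dcols = dcols.reshape(b, hout, wout, cin, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((b, cin, h + 2 * pad, w + 2 * pad))
        for a in range(kh):
            for c in range(kw):
                dxp[:, :, a : a + stride * hout : stride, c : c + stride * wout : stride] += (
                    dcols[:, :, :, :, a, c]
                )
        x._accum(dxp[:, :, pad : pad + h, pad : pad + w] if pad else dxp)

    out._backward = bwd
    return out


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalisation; updates running stats in place when
    training."""
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    out = Tensor(
        gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None],
        parents=(x, gamma, beta),
    )
    n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def bwd(g):
        gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        beta._accum(g.sum(axis=(0, 2, 3)))
        gx = g * gamma.data[None, :, None, None]
        if training:
            sum_gx = gx.sum(axis=(0, 2, 3), keepdims=True)
            sum_gx_xhat = (gx * xhat).sum(axis=(0, 2, 3), keepdims=True)
            dx = (gx - sum_gx / n - xhat * sum_gx_xhat / n) * inv[None, :, None, None]
        else:
            dx = gx * inv[None, :, None, None]
        x._accum(dx)

    out._backward = bwd
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)
    out = Tensor(out_data, parents=(x,))
    b, c, h, w = x.shape

    def bwd(g):
        x._accum(g.reshape(b, c, h, 2, w, 2).sum(axis=(3, 5)))

    out._backward = bwd
    return out


def crop2d(x: Tensor, h: int, w: int) -> Tensor:
    """Crop the trailing spatial dims to (h, w) (top-left anchored)."""
    if x.shape[2] == h and x.shape[3] == w:
        return x
    out = Tensor(x.data[:, :, :h, :w], parents=(x,))

    def bwd(g):
        full = np.zeros_like(x.data)
        full[:, :, :h, :w] = g
        x._accum(full)

    out._backward = bwd
    return out


def softmax_hw(x: Tensor) -> Tensor:
    """Softmax over the flattened spatial dimensions of (..., H, W)."""
    flat = x.data.reshape(*x.shape[:-2], -1)
    z = np.exp(flat - flat.max(axis=-1, keepdims=True))
    p = (z / z.sum(axis=-1, keepdims=True)).reshape(x.shape)
    out = Tensor(p, parents=(x,))

    def bwd(g):
        gp = (g * p).sum(axis=(-2, -1), keepdims=True)
        x._accum(p * (g - gp))

    out._backward = bwd
    return out


def dsnt_coords(probs: Tensor, xgrid: np.ndarray, ygrid: np.ndarray) -> Tensor:
    """Expected (x, y) over normalised heatmaps (..., H, W) -> (..., 2)."""
    px = (probs.data * xgrid[None, :]).sum(axis=(-2, -1))
    py = (probs.data * ygrid[:, None]).sum(axis=(-2, -1))
    out = Tensor(np.stack([px, py], axis=-1), parents=(probs,))

    def bwd(g):
        gx = g[..., 0][..., None, None] * xgrid[None, :]
        gy = g[..., 1][..., None, None] * ygrid[:, None]
        probs._accum(gx + gy)

    out._backward = bwd
    return out


def wing(x: Tensor, w: float, eps: float) -> Tensor:
    """Elementwise Wing loss."""
    ax = np.abs(x.data)
    c = w - w * np.log1p(w / eps)
    out = Tensor(np.where(ax < w, w * np.log1p(ax / eps), ax - c), parents=(x,))
    dydx = np.sign(x.data) * np.where(ax < w, w / (eps + ax), 1.0)
    out._backward = lambda g: x._accum(g * dydx)
    return out


def js_to_target(probs: Tensor, target: np.ndarray, tiny: float = 1e-12) -> Tensor:
    """Mean Jensen-Shannon divergence of normalised heatmaps (..., H, W)
    against constant targets of the same shape."""
    p = np.clip(probs.data, tiny, None)
    t = np.clip(target, tiny, None)
    m = (p + t) / 2.0
    n_maps = int(np.prod(p.shape[:-2])) or 1
    js = 0.5 * (p * np.log(p / m) + t * np.log(t / m)).sum() / n_maps
    out = Tensor(js, parents=(probs,))
    out._backward = lambda g: probs._accum(g * 0.5 * np.log(p / m) / n_maps)
    return out


class Adam:
    """Adaptive-moment estimation optimiser over a list of parameters."""

    def __init__(self, params: list[Tensor], lr: float = 0.005, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
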