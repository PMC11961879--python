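"""Minimal reverse-mode autodiff core for 3D convolutional networks.

Self-contained numpy implementation of exactly the operations the dose
prediction network family needs: 3D convolution (stride 1 and 2), instance
normalization, ReLU / sigmoid, trilinear 2x upsampling, channel
concatenation, global average pooling, fully connected layers, channel-wise
scaling and the L1 training loss.  Gradients are verified against central
finite differences in the test suite.

The convolution is evaluated as a sum over kernel offsets of strided slices
contracted with per-offset weight matrices, which keeps memory linear in the
input and routes the arithmetic through BLAS.
"""

from __future__ import annotations

from typing import Callable, Iterable, List, Sequence, Tuple

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Conv3d",
    "Linear",
    "InstanceNorm3d",
    "SEGate",
    "SEResBlock",
    "concat",
    "relu",
    "sigmoid",
    "add",
    "global_avg_pool",
    "channel_scale",
    "upsample2x",
    "l1_loss",
]


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None) -> None:
        """Reverse-mode accumulation from this node (scalar unless grad given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if isinstance(t, Parameter) or t._backward is None:
                t.grad = g if t.grad is None else t.grad + g
                continue
            for parent, pg in zip(t._parents, t._backward(g)):
                if not parent.requires_grad or pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)


class Parameter(Tensor):
    """A learnable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise ops
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        return (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        )

    return Tensor(out_data, parents=(a, b), backward=backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, parents=(x,), backward=lambda g: (g * mask,))


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor(s, parents=(x,), backward=lambda g: (g * s * (1.0 - s),))


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """3D cross-correlation with symmetric zero padding.

    x: (N, Ci, D, H, W); w: (Co, Ci, kd, kh, kw); b: (Co,).
    """
    xd, wd, bd = x.data, w.data, b.data
    N, Ci, D, H, W = xd.shape
    Co, Ci2, kd, kh, kw = wd.shape
    if Ci != Ci2:
        raise ValueError(f"channel mismatch: input has {Ci}, kernel expects {Ci2}")
    if pad:
        xp = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    else:
        xp = xd
    Do = (D + 2 * pad - kd) // stride + 1
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (W + 2 * pad - kw) // stride + 1
    P = Do * Ho * Wo
    K = kd * kh * kw

    def offset_slices(i, j, k):
        return (
            slice(None),
            slice(None),
            slice(i, i + Do * stride, stride),
            slice(j, j + Ho * stride, stride),
            slice(k, k + Wo * stride, stride),
        )

    # im2col: one (N, Ci*K, P) buffer -> a single BLAS matmul per conv
    cols = np.empty((N, Ci * K, P), dtype=xd.dtype)
    idx = 0
    for i in range(kd):
        for j in range(kh):
            for k in range(kw):
                cols[:, idx * Ci : (idx + 1) * Ci, :] = xp[offset_slices(i, j, k)].reshape(
                    N, Ci, P
                )
                idx += 1
    w2 = wd.transpose(2, 3, 4, 0, 1).reshape(K, Co, Ci).transpose(1, 0, 2).reshape(Co, K * Ci)
    out = (np.matmul(w2, cols)).reshape(N, Co, Do, Ho, Wo) + bd.reshape(1, Co, 1, 1, 1)

    def backward(g):
        g2 = np.ascontiguousarray(g.reshape(N, Co, P))
        db = g.sum(axis=(0, 2, 3, 4))
        # (N, Co, P) x (N, P, Ci*K) summed over batch
        dw2 = np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0)
        dw = (
            dw2.reshape(Co, K, Ci)
            .transpose(1, 0, 2)
            .reshape(kd, kh, kw, Co, Ci)
            .transpose(3, 4, 0, 1, 2)
        )
        dcols = np.matmul(w2.T, g2)  # (N, Ci*K, P)
        dxp = np.zeros_like(xp)
        idx = 0
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    dxp[offset_slices(i, j, k)] += dcols[
                        :, idx * Ci : (idx + 1) * Ci, :
                    ].reshape(N, Ci, Do, Ho, Wo)
                    idx += 1
        dx = dxp[:, :, pad : pad + D, pad : pad + H, pad : pad + W] if pad else dxp
        return dx, dw, db

    return Tensor(out, parents=(x, w, b), backward=backward)


# ---------------------------------------------------------------------------
# normalization / pooling / upsampling
# ---------------------------------------------------------------------------

def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization over the spatial dimensions."""
    xd = x.data
    axes = (2, 3, 4)
    mu = xd.mean(axis=axes, keepdims=True)
    var = xd.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu) * inv
    gd = gamma.data.reshape(1, -1, 1, 1, 1)
    bd = beta.data.reshape(1, -1, 1, 1, 1)
    out = gd * xhat + bd

    def backward(g):
        dgamma = (g * xhat).sum(axis=(0, 2, 3, 4))
        dbeta = g.sum(axis=(0, 2, 3, 4))
        gh = g * gd
        m1 = gh.mean(axis=axes, keepdims=True)
        m2 = (gh * xhat).mean(axis=axes, keepdims=True)
        dx = inv * (gh - m1 - xhat * m2)
        return dx, dgamma, dbeta

    return Tensor(out, parents=(x, gamma, beta), backward=backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, D, H, W) -> (N, C) spatial mean."""
    xd = x.data
    P = xd.shape[2] * xd.shape[3] * xd.shape[4]
    out = xd.mean(axis=(2, 3, 4))

    def backward(g):
        return (np.broadcast_to(g[:, :, None, None, None] / P, xd.shape).copy(),)

    return Tensor(out, parents=(x,), backward=backward)


def channel_scale(x: Tensor, s: Tensor) -> Tensor:
    """Scale (N, C, D, H, W) features by per-channel weights s of shape (N, C)."""
    sd = s.data[:, :, None, None, None]
    out = x.data * sd

    def backward(g):
        return g * sd, (g * x.data).sum(axis=(2, 3, 4))

    return Tensor(out, parents=(x, s), backward=backward)


def _up_axis(a: np.ndarray, axis: int) -> np.ndarray:
    a = np.moveaxis(a, axis, -1)
    n = a.shape[-1]
    oe = 0.75 * a
    oe[..., 1:] += 0.25 * a[..., :-1]
    oe[..., 0] += 0.25 * a[..., 0]
    oo = 0.75 * a
    oo[..., :-1] += 0.25 * a[..., 1:]
    oo[..., -1] += 0.25 * a[..., -1]
    out = np.empty(a.shape[:-1] + (2 * n,), dtype=a.dtype)
    out[..., 0::2] = oe
    out[..., 1::2] = oo
    return np.moveaxis(out, -1, axis)


def _up_axis_adjoint(g: np.ndarray, axis: int) -> np.ndarray:
    g = np.moveaxis(g, axis, -1)
    ge = g[..., 0::2]
    go = g[..., 1::2]
    da = 0.75 * (ge + go)
    da[..., :-1] += 0.25 * ge[..., 1:]
    da[..., 0] += 0.25 * ge[..., 0]
    da[..., 1:] += 0.25 * go[..., :-1]
    da[..., -1] += 0.25 * go[..., -1]
    return np.moveaxis(da, -1, axis)


def upsample2x(x: Tensor) -> Tensor:
    """Trilinear x2 upsampling of (N, C, D, H, W), voxel-center aligned."""
    out = x.data
    for axis in (2, 3, 4):
        out = _up_axis(out, axis)

    def backward(g):
        for axis in (2, 3, 4):
            g = _up_axis_adjoint(g, axis)
        return (g,)

    return Tensor(out, parents=(x,), backward=backward)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """x: (N, F) @ w: (F, O) + b: (O,)."""
    out = x.data @ w.data + b.data

    def backward(g):
        return g @ w.data.T, x.data.T @ g, g.sum(axis=0)

    return Tensor(out, parents=(x, w, b), backward=backward)


def l1_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean absolute error over every element (the training loss)."""
    target = np.asarray(target, dtype=pred.data.dtype)
    if target.shape != pred.data.shape:
        raise ValueError(f"shape mismatch: {pred.data.shape} vs {target.shape}")
    diff = pred.data - target
    out = np.abs(diff).mean()

    def backward(g):
        return (g * np.sign(diff) / diff.size,)

    return Tensor(out, parents=(pred,), backward=backward)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    """Container of parameters and sub-modules with recursive discovery."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> List[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def zero_all_parameters(self) -> None:
        """Set every learnable value to zero (used by the algebraic identities)."""
        for p in self.parameters():
            p.data = np.zeros_like(p.data)

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise ValueError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name]).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv3d(Module):
    def __init__(
        self,
        cin: int,
        cout: int,
        kernel: int = 3,
        stride: int = 1,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        self.stride = stride
        self.pad = kernel // 2
        fan_in = cin * kernel**3
        std = float(np.sqrt(2.0 / fan_in))
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Parameter(rng.normal(0.0, std, (cout, cin, kernel, kernel, kernel)).astype(dtype))
        self.bias = Parameter(np.zeros(cout, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng if rng is not None else np.random.default_rng(0)
        std = float(np.sqrt(2.0 / fin))
        self.weight = Parameter(rng.normal(0.0, std, (fin, fout)).astype(dtype))
        self.bias = Parameter(np.zeros(fout, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return linear(x, self.weight, self.bias)


class InstanceNorm3d(Module):
    def __init__(self, channels: int, dtype=np.float32):
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return instance_norm(x, self.gamma, self.beta)


class SEGate(Module):
    """Squeeze-and-excitation channel gating: GAP -> FC -> ReLU -> FC -> sigmoid."""

    def __init__(self, channels: int, reduction: int, rng=None, dtype=np.float32):
        if channels % reduction:
            raise ValueError(f"se reduction {reduction} does not divide {channels} channels")
        hidden = channels // reduction
        self.fc1 = Linear(channels, hidden, rng, dtype)
        self.fc2 = Linear(hidden, channels, rng, dtype)

    def forward(self, x: Tensor) -> Tensor:
        s = global_avg_pool(x)
        s = sigmoid(self.fc2(relu(self.fc1(s))))
        return channel_scale(x, s)


class SEResBlock(Module):
    """Residual block with SE channel gating on the branch.

    out = x + SE(Conv(ReLU(Norm(Conv(x))))) — shape preserving.
    """

    def __init__(self, channels: int, reduction: int = 4, rng=None, dtype=np.float32):
        self.conv1 = Conv3d(channels, channels, 3, 1, rng, dtype)
        self.norm = InstanceNorm3d(channels, dtype)
        self.conv2 = Conv3d(channels, channels, 3, 1, rng, dtype)
        self.se = SEGate(channels, reduction, rng, dtype)

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv1(x)
        y = self.norm(y)
        y = relu(y)
        y = self.conv2(y)
        y = self.se(y)
        return add(x, y)
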