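"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations a multi-resolution heatmap-regression
network needs: 2-D convolution (im2col), batch normalization, ReLU,
elementwise addition, bilinear resampling, channel concatenation and mean
squared error.  Gradients flow through a dynamically built tape; ``backward``
on a scalar loss topologically sorts the tape and accumulates gradients.

All arrays are float32 unless a caller supplies float64 explicitly.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "conv2d",
    "batch_norm2d",
    "relu",
    "add",
    "concat",
    "upsample_bilinear",
    "mse",
]


class Tensor:
    """A numpy array plus gradient bookkeeping.

    Parameters are Tensors with ``requires_grad=True``; intermediate results
    carry closures that push gradients to their parents.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this scalar through the recorded tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free tape references so intermediates can be collected
            node._backward = None
            node._parents = ()


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _track(out: Tensor, parents, backward) -> Tensor:
    if not _GRAD_ENABLED:
        return out
    needed = [p for p in parents if p.requires_grad or p._parents]
    if needed:
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# im2col convolution

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    cols = np.empty((b, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(b, c * kh * kw, oh * ow), oh, ow


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    b, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    cols = cols.reshape(b, c, kh, kw, oh, ow)
    xp = np.zeros((b, c, hp, wp), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols[:, :, i, j]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution, NCHW layout, square kernel."""
    cout, cin, kh, kw = weight.shape
    if x.shape[1] != cin:
        raise ValueError(f"conv2d: input has {x.shape[1]} channels, weight expects {cin}")
    cols, oh, ow = _im2col(x.data, kh, kw, stride, pad)
    wmat = weight.data.reshape(cout, -1)
    out = np.matmul(wmat, cols)  # (B, cout, oh*ow)
    if bias is not None:
        out += bias.data[:, None]
    b = x.shape[0]
    out = Tensor(out.reshape(b, cout, oh, ow))

    def backward(g: np.ndarray) -> None:
        gmat = g.reshape(b, cout, oh * ow)
        if weight.requires_grad:
            weight._accumulate(
                np.einsum("bcl,bkl->ck", gmat, cols).reshape(weight.shape)
            )
        if bias is not None and bias.requires_grad:
            bias._accumulate(gmat.sum(axis=(0, 2)))
        if x.requires_grad or x._parents:
            dcols = np.matmul(wmat.T, gmat)
            x._accumulate(_col2im(dcols, x.shape, kh, kw, stride, pad))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _track(out, parents, backward)


# ---------------------------------------------------------------------------

def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (B, H, W).

    In training mode batch statistics are used and the running estimates are
    updated in place; in evaluation mode the running estimates are used and
    the op is a fixed affine map.
    """
    xd = x.data
    n = xd.shape[0] * xd.shape[2] * xd.shape[3]
    if training:
        mean = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        unbiased = var * (n / max(n - 1, 1))
        running_var *= 1.0 - momentum
        running_var += momentum * unbiased
    else:
        mean = running_mean
        var = running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mean[:, None, None]) * inv_std[:, None, None]
    out = Tensor(gamma.data[:, None, None] * xhat + beta.data[:, None, None])

    def backward(g: np.ndarray) -> None:
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            gs = gamma.data[:, None, None] * inv_std[:, None, None]
            if training:
                gm = g.mean(axis=(0, 2, 3))[:, None, None]
                gxm = (g * xhat).mean(axis=(0, 2, 3))[:, None, None]
                x._accumulate(gs * (g - gm - xhat * gxm))
            else:
                x._accumulate(gs * g)

    return _track(out, (x, gamma, beta), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0))

    def backward(g: np.ndarray) -> None:
        if x.requires_grad or x._parents:
            x._accumulate(g * mask)

    return _track(out, (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ValueError(f"add: shape mismatch {a.shape} vs {b.shape}")
    out = Tensor(a.data + b.data)

    def backward(g: np.ndarray) -> None:
        if a.requires_grad or a._parents:
            a._accumulate(g)
        if b.requires_grad or b._parents:
            b._accumulate(g)

    return _track(out, (a, b), backward)


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the channel axis."""
    out = Tensor(np.concatenate([t.data for t in tensors], axis=1))
    sizes = [t.shape[1] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad or t._parents:
                t._accumulate(g[:, lo:hi])

    return _track(out, tuple(tensors), backward)


def _interp_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (n_out, n_in), half-pixel centers."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = src - i0
    m[np.arange(n_out), i0] += 1.0 - w1
    m[np.arange(n_out), i1] += w1
    return m


def upsample_bilinear(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear resize to ``out_hw``; separable, exact transpose in backward."""
    h_out, w_out = out_hw
    _, _, h_in, w_in = x.shape
    if (h_in, w_in) == (h_out, w_out):
        return x
    rmat = _interp_matrix(h_in, h_out, x.data.dtype)
    cmat = _interp_matrix(w_in, w_out, x.data.dtype)
    out = Tensor(rmat @ x.data @ cmat.T)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad or x._parents:
            x._accumulate(rmat.T @ g @ cmat)

    return _track(out, (x,), backward)


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error against a constant target; scalar output."""
    target = np.asarray(target, dtype=pred.data.dtype)
    if target.shape != pred.data.shape:
        raise ValueError(f"mse: shape mismatch {pred.data.shape} vs {target.shape}")
    diff = pred.data - target
    out = Tensor(np.asarray(np.mean(diff * diff)))

    def backward(g: np.ndarray) -> None:
        if pred.requires_grad or pred._parents:
            pred._accumulate((2.0 / diff.size) * diff * g)

    return _track(out, (pred,), backward)
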