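"""Minimal reverse-mode autodiff over numpy arrays for small 3D conv nets.

Everything runs single-sample (channel-first ``(C, D, H, W)`` volumes,
batch size 1), which is exactly the training regime simulated here: one
random patch per case per federated round. Supported primitives are the
ones a residual 3D U-Net needs — 3D convolution (any stride), 2x2x2
stride-2 transposed convolution, instance normalization, leaky ReLU,
sigmoid, channel concatenation, addition — plus the mirrored soft-Dice
loss as a fused op with an analytic gradient.

Pure numpy keeps the whole pipeline bit-reproducible on CPU, which the
federated-vs-centralized equivalence checks rely on. Arrays keep their
incoming dtype (float32 for training, float64 in gradient checks).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "param", "const", "backward",
    "add", "concat", "leaky_relu", "sigmoid", "instance_norm",
    "conv3d", "conv_transpose2", "mirrored_soft_dice_loss",
]


class Tensor:
    """A node in the computation graph: value, gradient, and pullbacks."""

    __slots__ = ("data", "grad", "parents", "requires_grad", "name")

    def __init__(self, data, parents=(), requires_grad=False, name=""):
        self.data = np.asarray(data)
        self.grad = None
        # parents: sequence of (parent_tensor, pullback) where pullback maps
        # the output gradient to this parent's gradient contribution
        self.parents = tuple(parents)
        self.requires_grad = requires_grad or any(p.requires_grad for p, _ in self.parents)
        self.name = name

    @property
    def shape(self):
        return self.data.shape


def param(data, name="") -> Tensor:
    return Tensor(data, requires_grad=True, name=name)


def const(data) -> Tensor:
    return Tensor(data)


def backward(out: Tensor, seed_grad=None) -> None:
    """Reverse-mode sweep from ``out``, accumulating ``.grad`` on the graph."""
    topo, seen = [], set()

    def visit(t):
        if id(t) in seen or not t.requires_grad:
            return
        seen.add(id(t))
        for p, _ in t.parents:
            visit(p)
        topo.append(t)

    visit(out)
    out.grad = np.ones_like(out.data) if seed_grad is None else np.asarray(seed_grad)
    for t in reversed(topo):
        for p, pull in t.parents:
            if not p.requires_grad:
                continue
            g = pull(t.grad)
            p.grad = g if p.grad is None else p.grad + g


def add(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data + b.data, parents=[(a, lambda g: g), (b, lambda g: g)])


def concat(a: Tensor, b: Tensor) -> Tensor:
    na = a.data.shape[0]
    return Tensor(
        np.concatenate([a.data, b.data], axis=0),
        parents=[(a, lambda g: g[:na]), (b, lambda g: g[na:])],
    )


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    mask = np.where(x.data > 0, 1.0, slope).astype(x.data.dtype)
    return Tensor(x.data * mask, parents=[(x, lambda g: g * mask)])


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable: exponentiate only negative magnitudes
    d = x.data
    e = np.exp(-np.abs(d))
    y = np.where(d >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
    return Tensor(y, parents=[(x, lambda g: g * y * (1.0 - y))])


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize each channel over its spatial extent, then scale and shift."""
    ax = (1, 2, 3)
    mu = x.data.mean(axis=ax, keepdims=True)
    var = x.data.var(axis=ax, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gcol = gamma.data.reshape(-1, 1, 1, 1)
    y = gcol * xhat + beta.data.reshape(-1, 1, 1, 1)
    n = x.data[0].size

    def pull_x(g):
        dxhat = g * gcol
        t1 = dxhat - dxhat.mean(axis=ax, keepdims=True)
        t2 = xhat * (dxhat * xhat).sum(axis=ax, keepdims=True) / n
        return inv * (t1 - t2)

    return Tensor(y, parents=[
        (x, pull_x),
        (gamma, lambda g: (g * xhat).sum(axis=ax).reshape(gamma.data.shape)),
        (beta, lambda g: g.sum(axis=ax).reshape(beta.data.shape)),
    ])


def _im2col(xp: np.ndarray, k: int, stride: int, out_sp: tuple) -> np.ndarray:
    cin = xp.shape[0]
    do, ho, wo = out_sp
    cols = np.empty((cin, k, k, k, do, ho, wo), dtype=xp.dtype)
    for a in range(k):
        for b in range(k):
            for c in range(k):
                cols[:, a, b, c] = xp[
                    :,
                    a: a + stride * do: stride,
                    b: b + stride * ho: stride,
                    c: c + stride * wo: stride,
                ]
    return cols.reshape(cin * k ** 3, do * ho * wo)


def _col2im(cols: np.ndarray, in_shape: tuple, k: int, stride: int, out_sp: tuple) -> np.ndarray:
    cin = in_shape[0]
    do, ho, wo = out_sp
    cols = cols.reshape(cin, k, k, k, do, ho, wo)
    xg = np.zeros(in_shape, dtype=cols.dtype)
    for a in range(k):
        for b in range(k):
            for c in range(k):
                xg[
                    :,
                    a: a + stride * do: stride,
                    b: b + stride * ho: stride,
                    c: c + stride * wo: stride,
                ] += cols[:, a, b, c]
    return xg


def conv3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    """3D cross-correlation; ``w`` is (Cout, Cin, k, k, k), ``b`` is (Cout,)."""
    cout, cin, k, _, _ = w.data.shape
    if x.data.shape[0] != cin:
        raise ValueError(f"conv3d: expected {cin} input channels, got {x.data.shape[0]}")
    xp = np.pad(x.data, ((0, 0),) + ((pad, pad),) * 3) if pad else x.data
    out_sp = tuple((s - k) // stride + 1 for s in xp.shape[1:])
    cols = _im2col(xp, k, stride, out_sp)
    wf = w.data.reshape(cout, -1)
    y = (wf @ cols + b.data[:, None]).reshape((cout,) + out_sp)
    pad_shape = xp.shape

    def pull_x(g):
        gf = g.reshape(cout, -1)
        xg = _col2im(wf.T @ gf, pad_shape, k, stride, out_sp)
        if pad:
            xg = xg[:, pad:-pad, pad:-pad, pad:-pad]
        return xg

    return Tensor(y, parents=[
        (x, pull_x),
        (w, lambda g: (g.reshape(cout, -1) @ cols.T).reshape(w.data.shape)),
        (b, lambda g: g.reshape(cout, -1).sum(axis=1)),
    ])


def conv_transpose2(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2x2x2 stride-2 transposed convolution (doubles each spatial dim).

    ``w`` is (Cin, Cout, 2, 2, 2); patches do not overlap at stride 2.
    """
    cin, cout = w.data.shape[:2]
    if x.data.shape[0] != cin:
        raise ValueError(f"conv_transpose2: expected {cin} input channels, got {x.data.shape[0]}")
    d, h, wd = x.data.shape[1:]
    t = np.tensordot(w.data, x.data, axes=([0], [0]))  # (Cout,2,2,2,D,H,W)
    y = t.transpose(0, 4, 1, 5, 2, 6, 3).reshape(cout, 2 * d, 2 * h, 2 * wd)
    y = y + b.data[:, None, None, None]

    def split(g):
        return g.reshape(cout, d, 2, h, 2, wd, 2).transpose(0, 2, 4, 6, 1, 3, 5)

    return Tensor(y, parents=[
        (x, lambda g: np.tensordot(w.data, split(g), axes=([1, 2, 3, 4], [0, 1, 2, 3]))),
        (w, lambda g: np.tensordot(x.data, split(g), axes=([1, 2, 3], [4, 5, 6]))),
        (b, lambda g: g.sum(axis=(1, 2, 3))),
    ])


def mirrored_soft_dice_loss(pred: Tensor, ref: np.ndarray) -> Tensor:
    """Mean over channels of 1 − soft-DSC(1 − ref, 1 − pred), with gradient.

    ``pred`` holds sigmoid values, ``ref`` binary reference channels of the
    same shape. If a channel's complements are both all-zero its term is 0.
    """
    if pred.data.shape != ref.shape:
        raise ValueError(f"shape mismatch: pred {pred.data.shape} vs ref {ref.shape}")
    p = pred.data
    g = 1.0 - np.asarray(ref, dtype=p.dtype)
    q = 1.0 - p
    nchan = p.shape[0]
    total = 0.0
    grad = np.zeros_like(p)
    for c in range(nchan):
        sg = g[c].sum()
        sq = q[c].sum()
        denom = sg + sq
        if denom == 0:
            continue
        sgq = (g[c] * q[c]).sum()
        total += 1.0 - 2.0 * sgq / denom
        # dL/dp = (1/C) * (2*g*denom - 2*sgq) / denom^2
        grad[c] = (2.0 * g[c] * denom - 2.0 * sgq) / (denom * denom) / nchan
    loss = np.asarray(total / nchan, dtype=p.dtype)
    return Tensor(loss, parents=[(pred, lambda gout: gout * grad)])
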