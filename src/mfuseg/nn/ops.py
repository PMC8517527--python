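"""Differentiable array operations for 2-D convolutional networks.

All image tensors are NCHW.  Convolutions are implemented as a sum over
kernel offsets: for each (i, j) inside the kernel a strided slice of the
padded input is contracted with the corresponding weight plane.  This keeps
peak memory at O(input) rather than the O(input * k^2) of an im2col buffer
while still going through BLAS for the channel contraction.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Var


def _pad2d(x: np.ndarray, p: int, value: float = 0.0) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=value)


def conv2d(x: Var, w: Var, b: Var | None, stride: int = 1, padding: int = 0) -> Var:
    """2-D cross-correlation with square kernel; w is (out, in, k, k)."""
    xd, wd = x.data, w.data
    n, cin, h, wi = xd.shape
    cout, cin_w, k, _ = wd.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input has {cin} channels, weight expects {cin_w}")
    xp = _pad2d(xd, padding)
    ho = (h + 2 * padding - k) // stride + 1
    wo = (wi + 2 * padding - k) // stride + 1
    # accumulate in channels-last layout, transpose once at the end
    acc = np.zeros((n, ho, wo, cout), dtype=xd.dtype)
    for i in range(k):
        for j in range(k):
            sl = xp[:, :, i : i + (ho - 1) * stride + 1 : stride, j : j + (wo - 1) * stride + 1 : stride]
            # (n,cin,ho,wo) x (cout,cin) -> (n,ho,wo,cout)
            acc += np.tensordot(sl, wd[:, :, i, j], axes=([1], [1]))
    y = np.ascontiguousarray(acc.transpose(0, 3, 1, 2))
    if b is not None:
        y += b.data[None, :, None, None]

    parents = [x, w] + ([b] if b is not None else [])

    def backward_fn(gy: np.ndarray) -> None:
        g = gy  # (n,cout,ho,wo)
        if b is not None and b.needs_grad():
            b.accumulate(g.sum(axis=(0, 2, 3)))
        need_x = x.needs_grad()
        need_w = w.needs_grad()
        if need_w:
            dw = np.empty_like(wd)
        if need_x:
            dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                hs = slice(i, i + (ho - 1) * stride + 1, stride)
                ws = slice(j, j + (wo - 1) * stride + 1, stride)
                if need_w:
                    # (n,cout,ho,wo) x (n,cin,ho,wo) -> (cout,cin)
                    dw[:, :, i, j] = np.tensordot(g, xp[:, :, hs, ws], axes=([0, 2, 3], [0, 2, 3]))
                if need_x:
                    # (n,cout,ho,wo) x (cout,cin) -> (n,ho,wo,cin)
                    dxp[:, :, hs, ws] += np.tensordot(g, wd[:, :, i, j], axes=([1], [0])).transpose(0, 3, 1, 2)
        if need_w:
            w.accumulate(dw)
        if need_x:
            if padding:
                x.accumulate(dxp[:, :, padding:-padding, padding:-padding])
            else:
                x.accumulate(dxp)

    return Var(y, parents=parents, backward_fn=backward_fn)


def batch_norm(
    x: Var,
    gamma: Var,
    beta: Var,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Var:
    """Per-channel batch normalization over (N, H, W).

    In training mode batch statistics normalise the activations and the
    running buffers are updated in place (unbiased variance, matching the
    usual framework convention); in eval mode the running buffers are used.
    """
    xd = x.data
    if training:
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        m = xd.shape[0] * xd.shape[2] * xd.shape[3]
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * (var * m / max(m - 1, 1))
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu[None, :, None, None]) * inv_std[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward_fn(gy: np.ndarray) -> None:
        if beta.needs_grad():
            beta.accumulate(gy.sum(axis=(0, 2, 3)))
        if gamma.needs_grad():
            gamma.accumulate((gy * xhat).sum(axis=(0, 2, 3)))
        if x.needs_grad():
            gscaled = gy * gamma.data[None, :, None, None]
            if training:
                m = xd.shape[0] * xd.shape[2] * xd.shape[3]
                mean_g = gscaled.mean(axis=(0, 2, 3))
                mean_gx = (gscaled * xhat).mean(axis=(0, 2, 3))
                dx = inv_std[None, :, None, None] * (
                    gscaled - mean_g[None, :, None, None] - xhat * mean_gx[None, :, None, None]
                )
            else:
                dx = gscaled * inv_std[None, :, None, None]
            x.accumulate(dx)

    return Var(y, parents=(x, gamma, beta), backward_fn=backward_fn)


def relu(x: Var) -> Var:
    mask = x.data > 0
    y = np.where(mask, x.data, 0.0)

    def backward_fn(gy: np.ndarray) -> None:
        if x.needs_grad():
            x.accumulate(gy * mask)

    return Var(y, parents=(x,), backward_fn=backward_fn)


def add(a: Var, b: Var) -> Var:
    y = a.data + b.data

    def backward_fn(gy: np.ndarray) -> None:
        if a.needs_grad():
            a.accumulate(gy)
        if b.needs_grad():
            b.accumulate(gy)

    return Var(y, parents=(a, b), backward_fn=backward_fn)


def concat(xs: list[Var], axis: int = 1) -> Var:
    y = np.concatenate([v.data for v in xs], axis=axis)
    sizes = [v.data.shape[axis] for v in xs]
    offsets = np.cumsum([0] + sizes)

    def backward_fn(gy: np.ndarray) -> None:
        for v, lo, hi in zip(xs, offsets[:-1], offsets[1:]):
            if v.needs_grad():
                idx = [slice(None)] * gy.ndim
                idx[axis] = slice(lo, hi)
                v.accumulate(gy[tuple(idx)])

    return Var(y, parents=tuple(xs), backward_fn=backward_fn)


def max_pool2d(x: Var, kernel: int = 3, stride: int = 2, padding: int = 1) -> Var:
    xd = x.data
    n, c, h, w = xd.shape
    xp = _pad2d(xd, padding, value=-np.inf)
    ho = (h + 2 * padding - kernel) // stride + 1
    wo = (w + 2 * padding - kernel) // stride + 1
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    win = win.reshape(n, c, ho, wo, kernel * kernel)
    idx = win.argmax(axis=-1)
    y = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    y = np.ascontiguousarray(y)

    def backward_fn(gy: np.ndarray) -> None:
        if not x.needs_grad():
            return
        di, dj = idx // kernel, idx % kernel
        rows = np.arange(ho)[None, None, :, None] * stride + di
        cols = np.arange(wo)[None, None, None, :] * stride + dj
        nn = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, :, None, None]
        dxp = np.zeros_like(xp)
        np.add.at(dxp, (nn, cc, rows, cols), gy)
        if padding:
            x.accumulate(dxp[:, :, padding:-padding, padding:-padding])
        else:
            x.accumulate(dxp)

    return Var(y, parents=(x,), backward_fn=backward_fn)


def upsample_nearest2(x: Var) -> Var:
    """Nearest-neighbour upsampling by a factor of 2 in both spatial dims."""
    xd = x.data
    y = xd.repeat(2, axis=2).repeat(2, axis=3)

    def backward_fn(gy: np.ndarray) -> None:
        if x.needs_grad():
            n, c, h2, w2 = gy.shape
            x.accumulate(gy.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return Var(y, parents=(x,), backward_fn=backward_fn)
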