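"""Differentiable ops on :class:`~grrdb.nn.tensor.Tensor`.

Feature maps are ``(N, C, H, W)`` arrays.  All convolutions are stride-1 with
odd kernels and zero-padded "same" semantics, so the input gradient of a
convolution is again a same-padded convolution with the spatially flipped
kernel — forward and both backward passes reduce to per-tap GEMMs with
shifted accumulation (no im2col gather).
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, as_tensor, grad_enabled


def _make(data, parents, backward):
    req = any(p.requires_grad for p in parents)
    if grad_enabled() and req:
        return Tensor(data, requires_grad=True, _parents=tuple(parents), _backward=backward)
    return Tensor(data)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (reverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    axes = tuple(i for i, (gs, ss) in enumerate(zip(g.shape, shape)) if ss == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b.accumulate_grad(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def sub(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data - b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b.accumulate_grad(_unbroadcast(-g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b.accumulate_grad(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def square(a):
    a = as_tensor(a)
    out_data = a.data * a.data

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(2.0 * a.data * g)

    return _make(out_data, (a,), backward)


def relu(a):
    a = as_tensor(a)
    mask = a.data > 0
    out_data = a.data * mask

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(g * mask)

    return _make(out_data, (a,), backward)


def leaky_relu(a, slope: float = 0.2):
    a = as_tensor(a)
    # single multiplier array serves forward and backward
    mult = np.where(a.data > 0, a.dtype.type(1.0), a.dtype.type(slope))
    out_data = a.data * mult

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(g * mult)

    return _make(out_data, (a,), backward)


def sigmoid(a):
    a = as_tensor(a)
    with np.errstate(over="ignore"):
        out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def mean(a):
    """Mean over all elements (scalar output)."""
    a = as_tensor(a)
    out_data = np.asarray(a.data.mean())

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(np.broadcast_to(g / a.data.size, a.shape).astype(a.dtype))

    return _make(out_data, (a,), backward)


def concat(tensors, axis: int = 1):
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t.accumulate_grad(p)

    return _make(out_data, tensors, backward)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def global_avg_pool(a):
    """(N,C,H,W) -> (N,C,1,1) spatial mean."""
    a = as_tensor(a)
    out_data = a.data.mean(axis=(2, 3), keepdims=True)
    hw = a.shape[2] * a.shape[3]

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(np.broadcast_to(g / hw, a.shape).astype(a.dtype))

    return _make(out_data, (a,), backward)


def global_max_pool(a):
    """(N,C,H,W) -> (N,C,1,1) spatial max; ties share the gradient."""
    a = as_tensor(a)
    out_data = a.data.max(axis=(2, 3), keepdims=True)

    def backward(g):
        if a.requires_grad:
            mask = (a.data == out_data).astype(g.dtype)
            mask /= mask.sum(axis=(2, 3), keepdims=True)
            a.accumulate_grad(mask * g)

    return _make(out_data, (a,), backward)


def channel_mean(a):
    """(N,C,H,W) -> (N,1,H,W) mean over channels."""
    a = as_tensor(a)
    out_data = a.data.mean(axis=1, keepdims=True)
    c = a.shape[1]

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(np.broadcast_to(g / c, a.shape).astype(a.dtype))

    return _make(out_data, (a,), backward)


def channel_max(a):
    """(N,C,H,W) -> (N,1,H,W) max over channels; ties share the gradient."""
    a = as_tensor(a)
    out_data = a.data.max(axis=1, keepdims=True)

    def backward(g):
        if a.requires_grad:
            mask = (a.data == out_data).astype(g.dtype)
            mask /= mask.sum(axis=1, keepdims=True)
            a.accumulate_grad(mask * g)

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# dense / convolution
# ---------------------------------------------------------------------------

def linear(x, w, b=None):
    """x:(N,C) @ w:(C,O) + b:(O,)."""
    x, w = as_tensor(x), as_tensor(w)
    out_data = x.data @ w.data
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data
        parents.append(b)

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad(g @ w.data.T)
        if w.requires_grad:
            w.accumulate_grad(x.data.T @ g)
        if b is not None and b.requires_grad:
            b.accumulate_grad(g.sum(axis=0))

    return _make(out_data, parents, backward)


def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _conv2d_raw(x: np.ndarray, w: np.ndarray, xp: np.ndarray | None = None) -> np.ndarray:
    """Forward conv, stride 1, same padding. x:(N,C,H,W), w:(O,C,kh,kw).

    Computed as one stacked GEMM over all kernel taps followed by shifted
    accumulation — avoids im2col's large gather copies.  ``xp`` may carry a
    pre-padded input.
    """
    n, c, h, ww = x.shape
    o, _, kh, kw = w.shape
    if kh == 1 and kw == 1:
        out = np.matmul(w.reshape(o, c), x.reshape(n, c, h * ww))
        return out.reshape(n, o, h, ww)
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    if xp is None:
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    hp, wp = h + 2 * ph, ww + 2 * pw
    xf = xp.reshape(n, c, hp * wp)
    ws = np.ascontiguousarray(w.transpose(2, 3, 0, 1)).reshape(kh * kw * o, c)
    t = np.matmul(ws, xf).reshape(n, kh, kw, o, hp, wp)
    out = np.zeros((n, o, h, ww), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            out += t[:, i, j, :, i:i + h, j:j + ww]
    return out


def conv2d(x, w, b=None):
    """Stride-1 same-padded 2-D convolution (cross-correlation convention).

    x: (N,C,H,W); w: (O,C,kh,kw) with kh,kw odd; b: (O,) or None.
    """
    x, w = as_tensor(x), as_tensor(w)
    o, ci, kh, kw = w.shape
    if x.shape[1] != ci:
        raise ValueError(f"conv2d: input has {x.shape[1]} channels, weight expects {ci}")
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    xpad = None
    if kh != 1 or kw != 1:
        xpad = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    out_data = _conv2d_raw(x.data, w.data, xpad)
    if not (grad_enabled() and (x.requires_grad or w.requires_grad)):
        xpad = None  # inference: no need to keep the padded copy alive
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        out_data += b.data.reshape(1, o, 1, 1)
        parents.append(b)

    def backward(g):
        n, c, h, ww = x.shape
        if w.requires_grad:
            gmat = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(o, n * h * ww)
            if kh == 1 and kw == 1:
                xs = np.ascontiguousarray(x.data.transpose(1, 0, 2, 3)).reshape(c, -1)
                w.accumulate_grad((gmat @ xs.T).reshape(w.shape))
            else:
                dw = np.empty_like(w.data)
                for i in range(kh):
                    for j in range(kw):
                        xs = np.ascontiguousarray(
                            xpad[:, :, i:i + h, j:j + ww].transpose(1, 0, 2, 3)).reshape(c, -1)
                        dw[:, :, i, j] = gmat @ xs.T
                w.accumulate_grad(dw)
        if x.requires_grad:
            # transpose of the conv: scatter each tap's (C,O) GEMM back
            hp, wp = h + 2 * ph, ww + 2 * pw
            gp = np.zeros((n, c, hp, wp), dtype=g.dtype)
            gf = g.reshape(n, o, h * ww)
            wt = w.data.transpose(1, 0, 2, 3)  # (C,O,kh,kw)
            for i in range(kh):
                for j in range(kw):
                    t = np.matmul(wt[:, :, i, j], gf).reshape(n, c, h, ww)
                    gp[:, :, i:i + h, j:j + ww] += t
            x.accumulate_grad(gp[:, :, ph:ph + h, pw:pw + ww])
        if b is not None and b.requires_grad:
            b.accumulate_grad(g.sum(axis=(0, 2, 3)))

    return _make(out_data, parents, backward)


def depthwise_conv2d(x, w, b=None, dilation: int = 1):
    """Per-channel (grouped, groups=C) convolution, stride 1, same padding.

    x: (N,C,H,W); w: (C,M,k,k) — M output maps per input channel, output has
    C*M channels ordered channel-major (c*M+m); b: (C*M,) or None.
    Dilation spaces the taps; padding keeps the footprint centred.
    Computed tap-by-tap as shifted scaled adds (no window materialization).
    """
    x, w = as_tensor(x), as_tensor(w)
    c, m, k, _ = w.shape
    if x.shape[1] != c:
        raise ValueError(f"depthwise_conv2d: input has {x.shape[1]} channels, weight expects {c}")
    n, _, h, ww = x.shape
    p = (dilation * (k - 1)) // 2
    xp = _pad_hw(x.data, p)
    out = np.zeros((n, c, m, h, ww), dtype=x.data.dtype)
    for i in range(k):
        for j in range(k):
            sl = xp[:, :, i * dilation:i * dilation + h, j * dilation:j * dilation + ww]
            if m == 1:
                out[:, :, 0] += w.data[None, :, 0, i, j, None, None] * sl
            else:
                out += w.data[None, :, :, i, j, None, None] * sl[:, :, None]
    out_data = out.reshape(n, c * m, h, ww)
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        out_data += b.data.reshape(1, c * m, 1, 1)
        parents.append(b)

    def backward(g):
        gr = g.reshape(n, c, m, h, ww)
        if w.requires_grad:
            xpb = _pad_hw(x.data, p)
            dw = np.empty_like(w.data)
            for i in range(k):
                for j in range(k):
                    sl = xpb[:, :, i * dilation:i * dilation + h, j * dilation:j * dilation + ww]
                    if m == 1:
                        dw[:, 0, i, j] = (sl * gr[:, :, 0]).sum(axis=(0, 2, 3))
                    else:
                        dw[:, :, i, j] = np.einsum("nchw,ncmhw->cm", sl, gr, optimize=True)
            w.accumulate_grad(dw)
        if x.requires_grad:
            hp, wp = h + 2 * p, ww + 2 * p
            gp = np.zeros((n, c, hp, wp), dtype=g.dtype)
            for i in range(k):
                for j in range(k):
                    if m == 1:
                        t = w.data[None, :, 0, i, j, None, None] * gr[:, :, 0]
                    else:
                        t = np.einsum("cm,ncmhw->nchw", w.data[:, :, i, j], gr, optimize=True)
                    gp[:, :, i * dilation:i * dilation + h, j * dilation:j * dilation + ww] += t
            x.accumulate_grad(gp[:, :, p:p + h, p:p + ww])
        if b is not None and b.requires_grad:
            b.accumulate_grad(g.sum(axis=(0, 2, 3)))

    return _make(out_data, parents, backward)


def clip01_ste(a):
    """Clamp to [0,1] with a straight-through gradient.

    Forward applies the same clipping stored images receive; backward passes
    the gradient through unchanged, so saturated pixels can still recover if
    the clipped value disagrees with the target.
    """
    a = as_tensor(a)
    out_data = np.clip(a.data, 0.0, 1.0)

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(g)

    return _make(out_data, (a,), backward)


def reshape(a, shape):
    a = as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(g.reshape(a.shape))

    return _make(out_data, (a,), backward)


def mse_loss(pred, target):
    """Mean of squared differences over every element of the batch."""
    pred, target = as_tensor(pred), as_tensor(target)
    if pred.shape != target.shape:
        raise ValueError(f"mse_loss: shape mismatch {pred.shape} vs {target.shape}")
    diff = pred.data - target.data
    out_data = np.asarray((diff * diff).mean())

    def backward(g):
        scale = 2.0 / diff.size
        if pred.requires_grad:
            pred.accumulate_grad((scale * g) * diff)
        if target.requires_grad:
            target.accumulate_grad((-scale * g) * diff)

    return _make(out_data, (pred, target), backward)
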