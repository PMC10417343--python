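"""Naive loop-based reference implementations used as independent oracles.

Everything here is written with explicit Python loops over output pixels and
deliberately shares no code with grrdb.nn.
"""

from __future__ import annotations

import numpy as np


def naive_conv2d(x: np.ndarray, w: np.ndarray, b=None) -> np.ndarray:
    """Stride-1 same-padded cross-correlation. x:(N,C,H,W), w:(O,C,kh,kw)."""
    n, c, h, ww = x.shape
    o, _, kh, kw = w.shape
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    out = np.zeros((n, o, h, ww))
    for ni in range(n):
        for oi in range(o):
            for y in range(h):
                for xx in range(ww):
                    acc = 0.0
                    for ci in range(c):
                        for i in range(kh):
                            for j in range(kw):
                                yy, xj = y + i - ph, xx + j - pw
                                if 0 <= yy < h and 0 <= xj < ww:
                                    acc += x[ni, ci, yy, xj] * w[oi, ci, i, j]
                    out[ni, oi, y, xx] = acc + (0.0 if b is None else b[oi])
    return out


def naive_depthwise(x: np.ndarray, w: np.ndarray, b=None, dilation: int = 1) -> np.ndarray:
    """Per-channel conv with M maps per channel. x:(N,C,H,W), w:(C,M,k,k)."""
    n, c, h, ww = x.shape
    _, m, k, _ = w.shape
    p = (dilation * (k - 1)) // 2
    out = np.zeros((n, c * m, h, ww))
    for ni in range(n):
        for ci in range(c):
            for mi in range(m):
                for y in range(h):
                    for xx in range(ww):
                        acc = 0.0
                        for i in range(k):
                            for j in range(k):
                                yy = y + i * dilation - p
                                xj = xx + j * dilation - p
                                if 0 <= yy < h and 0 <= xj < ww:
                                    acc += x[ni, ci, yy, xj] * w[ci, mi, i, j]
                        oc = ci * m + mi
                        out[ni, oc, y, xx] = acc + (0.0 if b is None else b[oc])
    return out


def naive_spatial_pool(x: np.ndarray):
    """Per-pixel channel mean and max maps, via loops. x:(N,C,H,W)."""
    n, c, h, w = x.shape
    mean = np.zeros((n, 1, h, w))
    mx = np.zeros((n, 1, h, w))
    for ni in range(n):
        for y in range(h):
            for xx in range(w):
                vals = [x[ni, ci, y, xx] for ci in range(c)]
                mean[ni, 0, y, xx] = sum(vals) / c
                mx[ni, 0, y, xx] = max(vals)
    return mean, mx


def naive_channel_pool(x: np.ndarray):
    """Per-channel global average and max vectors, via loops."""
    n, c, h, w = x.shape
    avg = np.zeros((n, c))
    mx = np.zeros((n, c))
    for ni in range(n):
        for ci in range(c):
            vals = [x[ni, ci, y, xx] for y in range(h) for xx in range(w)]
            avg[ni, ci] = sum(vals) / (h * w)
            mx[ni, ci] = max(vals)
    return avg, mx


def naive_dab_combine(w, s1, s2, xout, literal=False):
    """Elementwise loop over the gated dual-attention fusion."""
    out = np.zeros_like(s1)
    it = np.nditer(s1, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        first = xout[idx] * (w[idx] if literal else (1.0 - w[idx]))
        out[idx] = (w[idx] * s1[idx] + first
                    + w[idx] * s2[idx] + xout[idx] * (1.0 - w[idx]))
    return out


def naive_mse(a: np.ndarray, b: np.ndarray) -> float:
    acc, n = 0.0, 0
    for x, y in zip(a.ravel(), b.ravel()):
        acc += (x - y) ** 2
        n += 1
    return acc / n


def finite_difference_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar f at x (float64)."""
    g = np.zeros_like(x)
    flat = x.ravel()
    gf = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f()
        flat[i] = orig - eps
        fm = f()
        flat[i] = orig
        gf[i] = (fp - fm) / (2 * eps)
    return g
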