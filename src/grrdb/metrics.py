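"""Training loss and image-quality metrics.

PSNR is ``10*log10(L^2 / MSE)`` with ``L`` the dynamic range (1.0 for
unit-scaled floats, 255 for 8-bit).  SSIM follows the windowed structural
similarity convention: local means, variances and covariance under an 11x11
Gaussian window (sigma 1.5), combined per pixel as

    SSIM = (2*mu_x*mu_y + c1)(2*sigma_xy + c2)
           / (mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2)

with c1 = (k1*L)^2, c2 = (k2*L)^2, k1 = 0.01, k2 = 0.03, then averaged over
the map with the half-window border cropped.  A ``windowed=False`` switch
computes the same formula from whole-image (global) statistics instead.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .nn import functional as _F
from .nn.tensor import Tensor

log = logging.getLogger(__name__)

K1 = 0.01
K2 = 0.03
SSIM_SIGMA = 1.5
SSIM_TRUNCATE = 3.5  # radius = int(3.5 * 1.5 + 0.5) = 5 -> 11x11 window
SSIM_WIN = 2 * int(SSIM_TRUNCATE * SSIM_SIGMA + 0.5) + 1


def mse(x: np.ndarray, y: np.ndarray) -> float:
    """Plain mean squared error between two equal-shape arrays."""
    x, y = np.asarray(x, dtype=np.float64), np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    d = x - y
    return float(np.mean(d * d))


def mse_loss(pred, target):
    """Differentiable batch MSE for training (accepts Tensors or arrays)."""
    if isinstance(pred, Tensor) or isinstance(target, Tensor):
        return _F.mse_loss(pred, target)
    return mse(pred, target)


def psnr(x: np.ndarray, y: np.ndarray, L: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` when the images are equal."""
    if L <= 0:
        raise ValueError("dynamic range L must be > 0")
    m = mse(x, y)
    if m == 0.0:
        return float("inf")
    return 10.0 * np.log10(L * L / m)


def _local_stats(img: np.ndarray) -> np.ndarray:
    return gaussian_filter(img, SSIM_SIGMA, truncate=SSIM_TRUNCATE)


def ssim(x: np.ndarray, y: np.ndarray, L: float = 1.0, windowed: bool = True) -> float:
    """Structural similarity index in [-1, 1] (1 = identical)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if L <= 0:
        raise ValueError("dynamic range L must be > 0")
    c1 = (K1 * L) ** 2
    c2 = (K2 * L) ** 2
    if not windowed:
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(), y.var()
        cov = float(np.mean((x - mx) * (y - my)))
        return float(((2 * mx * my + c1) * (2 * cov + c2))
                     / ((mx * mx + my * my + c1) * (vx + vy + c2)))
    if min(x.shape) < SSIM_WIN:
        raise ValueError(
            f"image {x.shape} smaller than the {SSIM_WIN}x{SSIM_WIN} SSIM window; "
            "use windowed=False for tiny images")
    ux, uy = _local_stats(x), _local_stats(y)
    uxx, uyy, uxy = _local_stats(x * x), _local_stats(y * y), _local_stats(x * y)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    cov = uxy - ux * uy
    smap = ((2 * ux * uy + c1) * (2 * cov + c2)) / ((ux * ux + uy * uy + c1) * (vx + vy + c2))
    pad = (SSIM_WIN - 1) // 2
    return float(smap[pad:-pad, pad:-pad].mean())


# ---------------------------------------------------------------------------
# per-level aggregation
# ---------------------------------------------------------------------------

@dataclass
class LevelStats:
    n: int
    psnr_db: float
    ssim: float


@dataclass
class MetricsReport:
    """Per-mold-level mean PSNR/SSIM over a test set."""

    per_level: dict[int, LevelStats]
    L: float = 1.0

    def to_rows(self) -> list[dict]:
        return [{"level": lvl, "n": s.n, "psnr_db": s.psnr_db, "ssim": s.ssim}
                for lvl, s in sorted(self.per_level.items())]

    def to_csv(self, path):
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["level", "n", "psnr_db", "ssim"])
            writer.writeheader()
            writer.writerows(self.to_rows())

    def to_json(self, path=None, **extra) -> str:
        payload = {"L": self.L, "levels": self.to_rows(), **extra}
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def evaluate_set(pairs, L: float = 1.0, windowed: bool = True) -> MetricsReport:
    """Mean PSNR/SSIM per mold level over (clean, test_image, mold_level)
    triples.  Infinite PSNR values (identical images) propagate into the mean
    as the documented +inf sentinel.  Empty levels are simply absent."""
    groups: dict[int, list[tuple[float, float]]] = {}
    for clean, test, level in pairs:
        p = psnr(clean, test, L)
        s = ssim(clean, test, L, windowed=windowed)
        groups.setdefault(int(level), []).append((p, s))
    if not groups:
        log.warning("evaluate_set: no pairs supplied; empty report")
    per_level = {}
    for level, vals in groups.items():
        ps = [v[0] for v in vals]
        mean_p = float("inf") if any(np.isinf(ps)) else float(np.mean(ps))
        per_level[level] = LevelStats(n=len(vals), psnr_db=mean_p,
                                      ssim=float(np.mean([v[1] for v in vals])))
    return MetricsReport(per_level=per_level, L=L)
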