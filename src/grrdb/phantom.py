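"""Synthetic terahertz-style grain phantoms with paired noise.

Real THz reflectance images of wheat kernels (after background removal) show
bright, roughly elliptical kernel-shaped blobs on an exactly-zero background,
with interior texture that degrades as mold progresses: the moldy interior
loses reflectance (nutrient loss) and becomes more speckled.  The phantoms
emulate exactly those *spatial* statistics — smooth radial kernel profiles,
multiplicative interior speckle, and a suppressed-intensity patch whose area
grows with mold level — not the underlying spectroscopy.

Mold level ``m`` in 0..3 (normal / slight / moderate / serious) maps by
default to speckle amplitude ``0.05 + 0.1*m`` and suppressed-area fraction
``0.15*m``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

log = logging.getLogger(__name__)

MOLD_LEVELS = (0, 1, 2, 3)
#: default mapping from mold level to texture parameters
def default_speckle_amp(mold_level: int) -> float:
    return 0.05 + 0.1 * mold_level


def default_decay_frac(mold_level: int) -> float:
    return 0.15 * mold_level


#: intensity multiplier inside the suppressed (decayed) patch
DECAY_ATTENUATION = 0.45
#: maximum placement retries per kernel before giving up on it
MAX_PLACEMENT_RETRIES = 50


@dataclass
class PhantomConfig:
    """Geometry and texture of one clean phantom image."""

    canvas_h: int = 128
    canvas_w: int = 128
    n_kernels: int = 5
    kernel_axis_range: tuple[float, float] = (8.0, 16.0)
    mold_level: int = 0
    speckle_amp: float | None = None  # None -> default mapping from mold_level
    decay_frac: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.canvas_h < 32 or self.canvas_w < 32:
            raise ValueError("canvas dimensions must be >= 32")
        if self.mold_level not in MOLD_LEVELS:
            raise ValueError("mold_level must be in 0..3")
        lo, hi = self.kernel_axis_range
        if not (0 < lo <= hi):
            raise ValueError("kernel_axis_range must satisfy 0 < min <= max")
        if 2 * hi >= min(self.canvas_h, self.canvas_w):
            raise ValueError("kernel axes must fit inside the canvas")
        if self.speckle_amp is None:
            self.speckle_amp = default_speckle_amp(self.mold_level)
        if self.decay_frac is None:
            self.decay_frac = default_decay_frac(self.mold_level)
        if not (0.0 <= self.speckle_amp <= 1.0):
            raise ValueError("speckle_amp must lie in [0, 1]")
        if not (0.0 <= self.decay_frac <= 1.0):
            raise ValueError("decay_frac must lie in [0, 1]")


@dataclass
class NoiseSpec:
    """Noise model applied to a clean phantom.

    ``awgn_snr``: zero-mean Gaussian with variance ``mean(clean^2) / 10^(snr_db/10)``
    (signal power = mean squared intensity over the whole image).
    ``awgn_sigma``: fixed-sigma Gaussian.  ``power_drift``: per-row
    multiplicative gain ``1 + drift_amp*g(row)`` with ``g`` a smooth random
    walk in [-1, 1], emulating source-power fluctuation during raster scan.
    """

    kind: str = "awgn_snr"
    snr_db: float = 30.0
    sigma: float = 0.0
    drift_amp: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("awgn_snr", "awgn_sigma", "power_drift"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0.0 <= self.drift_amp < 1.0):
            raise ValueError("drift_amp must lie in [0, 1)")


@dataclass
class PairedSample:
    clean: np.ndarray
    noisy: np.ndarray
    mold_level: int
    noise: NoiseSpec
    id: str

    def __post_init__(self):
        if self.clean.shape != self.noisy.shape:
            raise ValueError("clean and noisy images must share a shape")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _ellipse_mask(h: int, w: int, cy: float, cx: float, a: float, b: float,
                  theta: float) -> tuple[np.ndarray, np.ndarray]:
    """Boolean mask and normalized elliptical radius r (r<1 inside)."""
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    r2 = u * u + v * v
    return r2 < 1.0, np.sqrt(r2)


def render_phantom(config: PhantomConfig) -> np.ndarray:
    """Render one clean phantom in [0,1]; background exactly zero.

    Kernels are rotated ellipses with a smooth radial profile peaking at the
    center.  Placement is best-effort: each kernel gets up to 50 rejection
    retries against overlap with already placed kernels (a one-pixel guard
    band keeps components disconnected); on failure the image simply carries
    fewer kernels and a warning is logged — never an error.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.canvas_h, config.canvas_w
    img = np.zeros((h, w), dtype=np.float64)
    occupied = np.zeros((h, w), dtype=bool)
    lo, hi = config.kernel_axis_range
    placed = 0
    for _ in range(config.n_kernels):
        for _attempt in range(MAX_PLACEMENT_RETRIES):
            a = rng.uniform(lo, hi)
            b = rng.uniform(lo, 0.75 * lo + 0.25 * hi)  # kernels are elongated
            if b > a:
                a, b = b, a
            theta = rng.uniform(0, np.pi)
            margin = a + 2.0
            if 2 * margin >= min(h, w):
                continue
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            # guard band: test a slightly inflated ellipse against occupancy
            guard, _ = _ellipse_mask(h, w, cy, cx, a + 2.0, b + 2.0, theta)
            if (occupied & guard).any():
                continue
            mask, r = _ellipse_mask(h, w, cy, cx, a, b, theta)
            peak = rng.uniform(0.75, 0.95)
            profile = peak * np.clip(1.0 - r ** 2, 0.0, None) ** 0.6
            tile = np.where(mask, profile, 0.0)
            if config.speckle_amp > 0:
                # smooth multiplicative speckle, zero-mean inside the kernel
                noise = gaussian_filter(rng.standard_normal((h, w)), sigma=1.5)
                scale = np.abs(noise[mask]).max()
                if scale > 0:
                    noise = noise / scale
                tile = tile * np.where(mask, 1.0 + config.speckle_amp * noise, 1.0)
            if config.decay_frac > 0:
                # suppressed-intensity patch: a sub-ellipse covering
                # decay_frac of the kernel area (axes scaled by sqrt(frac))
                s = np.sqrt(config.decay_frac)
                off_r = (1.0 - s) * 0.6
                ocy = cy + rng.uniform(-off_r, off_r) * b
                ocx = rng.uniform(-off_r, off_r) * a * np.cos(theta) + cx
                patch, _ = _ellipse_mask(h, w, ocy, ocx, a * s, b * s, theta)
                tile = np.where(patch & mask, tile * DECAY_ATTENUATION, tile)
            img = np.where(mask, tile, img)
            occupied |= guard
            placed += 1
            break
        else:
            log.warning("phantom: could not place kernel %d/%d after %d retries",
                        placed + 1, config.n_kernels, MAX_PLACEMENT_RETRIES)
    np.clip(img, 0.0, 1.0, out=img)
    return img


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def add_noise(clean: np.ndarray, spec: NoiseSpec,
              return_snr: bool = False):
    """Apply ``spec`` to ``clean``; result clipped to [0,1].

    With ``return_snr`` the empirical pre-clip SNR in dB
    (``10*log10(sum(clean^2)/sum(noise^2))``) is returned alongside.
    """
    clean = np.asarray(clean, dtype=np.float64)
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "awgn_snr":
        power = float(np.mean(clean ** 2))
        var = power / (10.0 ** (spec.snr_db / 10.0))
        perturbed = clean + rng.normal(0.0, np.sqrt(var), clean.shape)
    elif spec.kind == "awgn_sigma":
        if spec.sigma == 0:
            perturbed = clean.copy()
        else:
            perturbed = clean + rng.normal(0.0, spec.sigma, clean.shape)
    elif spec.kind == "power_drift":
        steps = rng.normal(0.0, 1.0, clean.shape[0])
        g = gaussian_filter(np.cumsum(steps), sigma=3.0, mode="nearest")
        peak = np.abs(g).max()
        if peak > 0:
            g = g / peak  # smooth random walk normalized into [-1, 1]
        perturbed = clean * (1.0 + spec.drift_amp * g)[:, None]
    else:  # pragma: no cover - guarded by NoiseSpec
        raise ValueError(f"unknown noise kind {spec.kind!r}")
    noisy = np.clip(perturbed, 0.0, 1.0)
    if return_snr:
        resid = perturbed - clean
        denom = float(np.sum(resid ** 2))
        snr = np.inf if denom == 0 else 10.0 * np.log10(float(np.sum(clean ** 2)) / denom)
        return noisy, snr
    return noisy


def make_pair(phantom_cfg: PhantomConfig, noise: NoiseSpec, sample_id: str) -> PairedSample:
    clean = render_phantom(phantom_cfg)
    noisy = add_noise(clean, noise)
    return PairedSample(clean=clean, noisy=noisy, mold_level=phantom_cfg.mold_level,
                        noise=noise, id=sample_id)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def generate_pairs(n_per_level: int, phantom_cfg: PhantomConfig | None = None,
                   noise: NoiseSpec | None = None, seed: int = 0) -> list[PairedSample]:
    """In-memory dataset: ``4*n_per_level`` paired samples, one sub-seed per
    sample derived as ``master_seed + i`` (i enumerates samples level-major).
    """
    if n_per_level < 1:
        raise ValueError("n_per_level must be >= 1")
    phantom_cfg = phantom_cfg or PhantomConfig()
    noise = noise or NoiseSpec()
    pairs = []
    i = 0
    for level in MOLD_LEVELS:
        for j in range(n_per_level):
            sub = seed + i
            pcfg = replace(phantom_cfg, mold_level=level, speckle_amp=None,
                           decay_frac=None, seed=sub)
            nspec = replace(noise, seed=sub + 500_000_000)
            pairs.append(make_pair(pcfg, nspec, sample_id=f"m{level}_{j:04d}"))
            i += 1
    return pairs


def generate_dataset(n_per_level: int, out_dir, phantom_cfg: PhantomConfig | None = None,
                     noise: NoiseSpec | None = None, seed: int = 0) -> Path:
    """Write paired 16-bit PNGs plus a CSV manifest; returns the manifest path."""
    from .cli_io import write_image  # deferred: avoid import cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = generate_pairs(n_per_level, phantom_cfg, noise, seed)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "mold_level", "clean_path", "noisy_path",
                         "noise_kind", "snr_db", "seed"])
        for p in pairs:
            clean_path = out_dir / f"{p.id}_clean.png"
            noisy_path = out_dir / f"{p.id}_noisy.png"
            write_image(p.clean, clean_path)
            write_image(p.noisy, noisy_path)
            writer.writerow([p.id, p.mold_level, clean_path.name, noisy_path.name,
                             p.noise.kind, p.noise.snr_db, p.noise.seed])
    return manifest


def load_dataset(manifest_path) -> list[PairedSample]:
    """Read a dataset previously written by :func:`generate_dataset`."""
    from .cli_io import read_image

    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    pairs = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            spec = NoiseSpec(kind=row["noise_kind"], snr_db=float(row["snr_db"]),
                             seed=int(row["seed"]))
            pairs.append(PairedSample(
                clean=read_image(root / row["clean_path"]),
                noisy=read_image(root / row["noisy_path"]),
                mold_level=int(row["mold_level"]),
                noise=spec, id=row["id"]))
    return pairs


def generate_cube(phantom_cfg: PhantomConfig, n_layers: int, seed: int = 0,
                  layer_drift: float = 0.1) -> np.ndarray:
    """Optional multi-layer 'frequency cube': one geometry, slowly varying
    kernel intensity across layers (a cosine ramp of relative amplitude
    ``layer_drift``); shape (n_layers, H, W)."""
    base = render_phantom(replace(phantom_cfg, seed=seed))
    k = np.arange(n_layers) / max(n_layers - 1, 1)
    gains = 1.0 - layer_drift * 0.5 * (1.0 - np.cos(2 * np.pi * k))
    cube = np.clip(base[None] * gains[:, None, None], 0.0, 1.0)
    return cube
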