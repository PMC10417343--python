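"""G-RRDB denoising network: Ghost-LKA front end, dense-residual (RRDB)
trunk, and a dual-attention (DAB) residual branch.

Architecture
------------
The model maps a single-channel intensity image to a same-shape denoised
image.  A 3x3 head convolution lifts the image to ``base_channels`` feature
maps.  Three Ghost-LKA blocks extract coarse, large-receptive-field features:
each applies large-kernel attention (LKA — a depthwise 5x5, a depthwise
dilated 7x7 and a pointwise convolution whose output multiplicatively gates
the input) followed by a ghost convolution (a cheap intrinsic/derived channel
split) and a residual sum.  The trunk is five residual-in-residual dense
blocks (RRDB): dense blocks whose convolutions see the concatenation of all
previous outputs, with every residual scaled by ``res_scale`` (0.2).  Two
dual-attention blocks (DAB) — spatial plus channel attention fused through a
sigmoid gate — form a residual branch over the trunk output.  Two 3x3
conv+ReLU layers and a final 1x1 convolution produce the residual estimate,
added to the network input when ``global_skip`` is on.

All spatial shapes are preserved (stride 1, same padding everywhere); with
every learnable weight zeroed each residual block is an exact identity, and
the zero-initialized tail makes the whole network start at the identity map.
"""

from __future__ import annotations

import io
import zipfile
from dataclasses import asdict, dataclass, replace

import numpy as np
import yaml

from . import nn
from .nn import functional as F


class ConfigError(ValueError):
    """Invalid architecture hyperparameter; the message names the field."""


@dataclass
class ModelConfig:
    """All architecture hyperparameters.

    ``growth`` defaults to ``base_channels // 2``; ``res_scale`` is the 0.2
    residual weighting applied inside and around every dense block.
    """

    in_channels: int = 1
    base_channels: int = 64
    n_ghost_lka: int = 3
    n_rrdb: int = 5
    n_dense_per_rrdb: int = 3
    n_conv_per_dense: int = 5
    growth: int | None = None
    res_scale: float = 0.2
    lrelu_slope: float = 0.2
    ghost_ratio: int = 2
    lka_dw_kernel: int = 5
    lka_dwd_kernel: int = 7
    lka_dilation: int = 3
    global_skip: bool = True
    n_dab: int = 2
    ca_reduction: int = 4
    sa_kernel: int = 7
    eq3_literal: bool = False
    rrdb_literal_residual: bool = False

    def __post_init__(self):
        if self.growth is None:
            self.growth = self.base_channels // 2
        self.validate()

    def validate(self):
        if self.in_channels < 1:
            raise ConfigError("in_channels must be >= 1")
        if self.base_channels < 1:
            raise ConfigError("base_channels must be >= 1")
        if self.ghost_ratio < 1:
            raise ConfigError("ghost_ratio must be >= 1")
        if self.base_channels % self.ghost_ratio != 0:
            raise ConfigError(
                f"base_channels ({self.base_channels}) must be divisible by ghost_ratio ({self.ghost_ratio})")
        if not (0.0 < self.res_scale <= 1.0):
            raise ConfigError("res_scale must lie in (0, 1]")
        if self.base_channels % self.ca_reduction != 0:
            raise ConfigError(
                f"base_channels ({self.base_channels}) must be divisible by ca_reduction ({self.ca_reduction})")
        for fname in ("n_ghost_lka", "n_rrdb", "n_dab"):
            if getattr(self, fname) < 0:
                raise ConfigError(f"{fname} must be >= 0")
        for fname in ("n_dense_per_rrdb", "n_conv_per_dense"):
            if getattr(self, fname) < 1:
                raise ConfigError(f"{fname} must be >= 1")
        for fname in ("lka_dw_kernel", "lka_dwd_kernel", "sa_kernel"):
            if getattr(self, fname) % 2 != 1:
                raise ConfigError(f"{fname} must be odd")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConfig":
        return cls(**yaml.safe_load(text))


def desk_config(**overrides) -> ModelConfig:
    """Small preset for CPU-scale experiments (16 channels)."""
    return ModelConfig(**{"base_channels": 16, **overrides})


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class LKABlock(nn.Module):
    """Large-kernel attention: DW 5x5 -> DW dilated 7x7 -> 1x1, then the
    result multiplicatively gates the input feature map."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        c = cfg.base_channels
        self.dw = nn.DepthwiseConv2d(c, cfg.lka_dw_kernel, rng)
        self.dwd = nn.DepthwiseConv2d(c, cfg.lka_dwd_kernel, rng, dilation=cfg.lka_dilation)
        self.pw = nn.Conv2d(c, c, 1, rng)

    def forward(self, x):
        attn = self.pw(self.dwd(self.dw(x)))
        return F.mul(attn, x)


class GhostConv(nn.Module):
    """Ghost convolution: a primary convolution produces ``out_ch/ratio``
    intrinsic maps; cheap depthwise 3x3 operations derive the remaining
    ``out_ch*(ratio-1)/ratio`` maps; both sets are concatenated.

    ``ratio=1`` degenerates to a plain convolution.
    """

    CHEAP_KERNEL = 3

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 ratio: int = 2, kernel: int = 3, bias: bool = True):
        if out_ch % ratio != 0:
            raise ConfigError(f"ghost conv: out_ch ({out_ch}) not divisible by ratio ({ratio})")
        self.ratio = ratio
        intrinsic = out_ch // ratio
        self.primary = nn.Conv2d(in_ch, intrinsic, kernel, rng, bias=bias)
        self.cheap = None
        if ratio > 1:
            self.cheap = nn.DepthwiseConv2d(intrinsic, self.CHEAP_KERNEL, rng,
                                            maps_per_channel=ratio - 1, bias=bias)

    def forward(self, x):
        p = self.primary(x)
        if self.cheap is None:
            return p
        return F.concat([p, self.cheap(p)], axis=1)


class GhostLKABlock(nn.Module):
    """LKA gating followed by a ghost convolution, with a residual sum back
    onto the block input (identity at zero weights)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        c = cfg.base_channels
        self.lka = LKABlock(cfg, rng)
        self.ghost = GhostConv(c, c, rng, ratio=cfg.ghost_ratio, kernel=3)

    def forward(self, x):
        return F.add(self.ghost(self.lka(x)), x)


class DenseBlock(nn.Module):
    """Densely connected convolutions with a scaled residual.

    Convolution ``k`` sees ``concat(x, y_1, ..., y_{k-1})``
    (``C + (k-1)*growth`` channels); all but the last are followed by a leaky
    ReLU; the last maps back to ``C`` channels and is added as
    ``x + res_scale * y_last``.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        c, g = cfg.base_channels, cfg.growth
        n = cfg.n_conv_per_dense
        self.res_scale = cfg.res_scale
        self.slope = cfg.lrelu_slope
        self.convs = [
            nn.Conv2d(c + k * g, g if k < n - 1 else c, 3, rng)
            for k in range(n)
        ]

    def forward(self, x):
        feats = [x]
        for k, conv in enumerate(self.convs):
            inp = feats[0] if len(feats) == 1 else F.concat(feats, axis=1)
            y = conv(inp)
            if k < len(self.convs) - 1:
                y = F.leaky_relu(y, self.slope)
                feats.append(y)
        return F.add(x, F.mul(y, self.res_scale))


class RRDB(nn.Module):
    """Residual-in-residual dense block: a chain of dense blocks wrapped in
    an outer residual, both scaled by ``res_scale``.

    The outer combination is ``x + res_scale * (chain(x) - x)`` so that the
    block is an exact identity when every weight is zero; the
    ``rrdb_literal_residual`` flag switches to the ESRGAN-style
    ``x + res_scale * chain(x)``.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.res_scale = cfg.res_scale
        self.literal = cfg.rrdb_literal_residual
        self.blocks = [DenseBlock(cfg, rng) for _ in range(cfg.n_dense_per_rrdb)]

    def forward(self, x):
        d = x
        for blk in self.blocks:
            d = blk(d)
        if self.literal:
            return F.add(x, F.mul(d, self.res_scale))
        return F.add(x, F.mul(F.sub(d, x), self.res_scale))


class SpatialAttention(nn.Module):
    """Channel-wise mean and max maps -> 7x7 conv -> sigmoid gate in (0,1),
    broadcast-multiplied with the input."""

    def __init__(self, rng: np.random.Generator, kernel: int = 7):
        self.conv = nn.Conv2d(2, 1, kernel, rng)

    def forward(self, x):
        pooled = F.concat([F.channel_mean(x), F.channel_max(x)], axis=1)
        w = F.sigmoid(self.conv(pooled))
        return F.mul(x, w)


class ChannelAttention(nn.Module):
    """Global average + max pooled channel vectors through a shared
    two-layer bottleneck, summed and sigmoided to per-channel gates."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        if channels % reduction != 0:
            raise ConfigError(f"channel attention: channels ({channels}) not divisible by reduction ({reduction})")
        self.channels = channels
        self.fc1 = nn.Linear(channels, channels // reduction, rng)
        self.fc2 = nn.Linear(channels // reduction, channels, rng)

    def _bottleneck(self, v):
        return self.fc2(F.relu(self.fc1(v)))

    def forward(self, x):
        n, c = x.shape[0], x.shape[1]
        avg = F.reshape(F.global_avg_pool(x), (n, c))
        mx = F.reshape(F.global_max_pool(x), (n, c))
        w = F.sigmoid(self._bottleneck(avg) + self._bottleneck(mx))
        return F.mul(x, F.reshape(w, (n, c, 1, 1)))


class DAB(nn.Module):
    """Dual-attention block.

    Spatial attention (s1) and channel attention (s2) are fused,
    ``Xa = s1 + s2``; a local 3x3 convolution and a global pooled bottleneck
    (broadcast spatially) are summed and sigmoided into a gate ``W`` strictly
    inside (0,1); the output combines the attention maps with a plain
    conv+ReLU feature branch ``Xout``:

        out = W*s1 + Xout*(1-W) + W*s2 + Xout*(1-W)

    (``eq3_literal`` replaces the first complementary term by ``Xout*W``).
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        c = cfg.base_channels
        self.eq3_literal = cfg.eq3_literal
        self.feat = nn.Conv2d(c, c, 3, rng)
        self.sa = SpatialAttention(rng, cfg.sa_kernel)
        self.ca = ChannelAttention(c, cfg.ca_reduction, rng)
        self.local = nn.Conv2d(c, c, 3, rng)
        self.glob1 = nn.Linear(c, c // cfg.ca_reduction, rng)
        self.glob2 = nn.Linear(c // cfg.ca_reduction, c, rng)

    def gate(self, xa):
        n, c = xa.shape[0], xa.shape[1]
        loc = self.local(xa)
        g = self.glob2(F.relu(self.glob1(F.reshape(F.global_avg_pool(xa), (n, c)))))
        return F.sigmoid(F.add(loc, F.reshape(g, (n, c, 1, 1))))

    @staticmethod
    def combine(w, s1, s2, xout, literal: bool = False):
        """The gated fusion of the attention and feature branches."""
        one_minus = F.sub(1.0, w)
        first = F.mul(xout, w) if literal else F.mul(xout, one_minus)
        return F.add(
            F.add(F.mul(w, s1), first),
            F.add(F.mul(w, s2), F.mul(xout, one_minus)),
        )

    def forward(self, x):
        xout = F.relu(self.feat(x))
        s1 = self.sa(x)
        s2 = self.ca(x)
        xa = F.add(s1, s2)
        w = self.gate(xa)
        return self.combine(w, s1, s2, xout, self.eq3_literal)


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

class GRRDB(nn.Module):
    """The assembled denoiser; built via :func:`build_grrdb`."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        c = cfg.base_channels
        self.cfg = cfg
        self.head = nn.Conv2d(cfg.in_channels, c, 3, rng)
        self.ghost_lka = [GhostLKABlock(cfg, rng) for _ in range(cfg.n_ghost_lka)]
        self.rrdbs = [RRDB(cfg, rng) for _ in range(cfg.n_rrdb)]
        self.dabs = [DAB(cfg, rng) for _ in range(cfg.n_dab)]
        self.tail1 = nn.Conv2d(c, c, 3, rng)
        self.tail2 = nn.Conv2d(c, c, 3, rng)
        # zero-init the output projection: with global_skip the network
        # starts at the identity, so early training cannot harm the image
        self.out_conv = nn.Conv2d(c, cfg.in_channels, 1, rng, zero_init=True)

    def forward(self, x):
        x = nn.as_tensor(x)
        if x.ndim == 3:
            x = F.reshape(x, (x.shape[0], 1, x.shape[1], x.shape[2]))
        t = self.head(x)
        for blk in self.ghost_lka:
            t = blk(t)
        for blk in self.rrdbs:
            t = blk(t)
        if self.dabs:
            b = t
            for blk in self.dabs:
                b = blk(b)
            t = F.add(t, b)
        t = F.relu(self.tail1(t))
        t = F.relu(self.tail2(t))
        out = self.out_conv(t)
        if self.cfg.global_skip:
            out = F.add(out, x)
        return out

    def denoise(self, images: np.ndarray, batch_size: int = 8, clip: bool = True) -> np.ndarray:
        """Denoise a (N,H,W) or (H,W) float array; returns the same shape."""
        single = images.ndim == 2
        arr = images[None] if single else images
        outs = []
        with nn.no_grad():
            for i in range(0, arr.shape[0], batch_size):
                batch = arr[i:i + batch_size].astype(nn.DTYPE)[:, None]
                y = self.forward(nn.Tensor(batch)).data[:, 0]
                outs.append(y)
        out = np.concatenate(outs, axis=0).astype(np.float64)
        if clip:
            out = np.clip(out, 0.0, 1.0)
        return out[0] if single else out

    def describe(self) -> str:
        lines = [f"G-RRDB: {self.n_parameters():,} parameters"]
        groups = [("head", self.head)]
        groups += [(f"ghost_lka[{i}]", b) for i, b in enumerate(self.ghost_lka)]
        groups += [(f"rrdb[{i}]", b) for i, b in enumerate(self.rrdbs)]
        groups += [(f"dab[{i}]", b) for i, b in enumerate(self.dabs)]
        groups += [("tail1", self.tail1), ("tail2", self.tail2), ("out_conv", self.out_conv)]
        for name, mod in groups:
            lines.append(f"  {name:<14s} {mod.n_parameters():>10,d} params")
        return "\n".join(lines)


def build_grrdb(cfg: ModelConfig | None = None, seed: int = 0, **overrides) -> GRRDB:
    """Build a seeded G-RRDB model; ``overrides`` patch fields of ``cfg``."""
    if cfg is None:
        cfg = ModelConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    cfg.validate()
    return GRRDB(cfg, np.random.default_rng(seed))


def variant_config(name: str, base: ModelConfig | None = None) -> ModelConfig:
    """Ablation variants: ``baseline`` (5 RRDB only), ``baseline_dab``
    (RRDB + DAB branch), ``grrdb`` (full)."""
    base = base or ModelConfig()
    if name == "baseline":
        return replace(base, n_ghost_lka=0, n_dab=0)
    if name == "baseline_dab":
        return replace(base, n_ghost_lka=0)
    if name == "grrdb":
        return replace(base)
    raise ConfigError(f"unknown variant {name!r}; expected baseline/baseline_dab/grrdb")


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: GRRDB, path):
    """Single zip archive: weights (npz) + the full config as YAML."""
    state = model.state_dict()
    buf = io.BytesIO()
    np.savez(buf, **state)
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("config.yaml", model.cfg.to_yaml())
        zf.writestr("weights.npz", buf.getvalue())


def load_checkpoint(path, cfg: ModelConfig | None = None) -> GRRDB:
    """Load a checkpoint; if ``cfg`` is given it must match the stored one."""
    with zipfile.ZipFile(path) as zf:
        stored = ModelConfig.from_yaml(zf.read("config.yaml").decode())
        if cfg is not None and asdict(cfg) != asdict(stored):
            raise ConfigError("checkpoint config does not match the requested config")
        with zf.open("weights.npz") as fh:
            state = dict(np.load(io.BytesIO(fh.read())))
    model = build_grrdb(stored)
    model.load_state_dict(state)
    return model
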