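"""Training and evaluation harness.

Protocol: Adam (initial learning rate 1e-3), batch size 8, MSE loss between
the network output on the noisy image and the clean reference, with the
dataset split 9:1 into train and test, stratified by mold level.  Two scales
are shipped as presets: the full-scale protocol (64 feature channels, 70
epochs) and a desk-scale preset (16 channels, 64x64 phantoms, a few epochs)
for CPU experiments.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np

from . import metrics, phantom
from .gnet import GRRDB, ModelConfig, build_grrdb, variant_config, save_checkpoint
from .nn import Adam, DTYPE, Tensor
from .nn import functional as F

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 8
    epochs: int = 70
    split: float = 0.9  # train fraction
    warmup_steps: int = 30  # linear ramp to lr; tames Adam's first steps
    schedule: str = "cosine"  # "cosine" decay after warmup, or "constant"
    min_lr_frac: float = 0.05  # cosine floor as a fraction of lr
    seed: int = 0
    checkpoint_every: int = 0  # 0 = only the best checkpoint
    optimizer: str = "adam"
    loss: str = "mse"

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0.0 < self.split < 1.0):
            raise ValueError("split fraction must lie in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.schedule not in ("cosine", "constant"):
            raise ValueError(f"unknown schedule {self.schedule!r}")


def desk_train_config(**overrides) -> TrainConfig:
    """Desk-scale preset: 5 epochs, otherwise the standard protocol."""
    return TrainConfig(**{"epochs": 5, **overrides})


@dataclass
class AblationSpec:
    variants: tuple[str, ...] = ("baseline", "baseline_dab", "grrdb")
    noise_levels_db: tuple[float, ...] = (20.0, 30.0, 40.0, 50.0)
    seeds: tuple[int, ...] = (0,)

    def __post_init__(self):
        if not self.variants:
            raise ValueError("at least one variant required")
        for v in self.variants:
            variant_config(v)  # validates the name
        if not all(np.isfinite(self.noise_levels_db)):
            raise ValueError("noise levels must be finite")


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------

def split_dataset(samples, ratio: float = 0.9, seed: int = 0):
    """Stratified train/test split by mold level.

    ``samples`` is a sequence with a ``mold_level`` attribute (or
    (id, level) pairs).  Returns (train_indices, test_indices) — an exact
    partition, deterministic in ``seed``.  A level with fewer than 2 samples
    is kept whole in train with a warning.
    """
    if len(samples) == 0:
        raise ValueError("empty dataset")
    levels = [getattr(s, "mold_level", s[1] if isinstance(s, tuple) else None)
              for s in samples]
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for level in sorted(set(levels)):
        idx = np.array([i for i, lv in enumerate(levels) if lv == level])
        if len(idx) < 2:
            log.warning("split: level %s has %d sample(s); kept whole in train", level, len(idx))
            train_idx.extend(idx.tolist())
            continue
        perm = rng.permutation(idx)
        n_test = max(1, int(round(len(idx) * (1.0 - ratio))))
        test_idx.extend(perm[:n_test].tolist())
        train_idx.extend(perm[n_test:].tolist())
    return sorted(train_idx), sorted(test_idx)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _lr_at(step: int, cfg: TrainConfig, total_steps: int) -> float:
    """Learning rate at optimizer step ``step`` (1-based).

    Linear warmup to the initial rate over ``warmup_steps``, then either a
    constant rate or a cosine decay to ``min_lr_frac * lr``.  The warmup
    tames Adam's renormalized first steps, which would otherwise throw the
    identity-initialized network far from its start; the decay lets the
    final steps settle instead of bouncing in an lr-sized neighbourhood.
    """
    ramp = min(1.0, step / cfg.warmup_steps) if cfg.warmup_steps > 0 else 1.0
    if cfg.schedule == "constant" or total_steps <= cfg.warmup_steps:
        return cfg.lr * ramp
    if step <= cfg.warmup_steps:
        return cfg.lr * ramp
    frac = (step - cfg.warmup_steps) / max(total_steps - cfg.warmup_steps, 1)
    cos = 0.5 * (1.0 + np.cos(np.pi * min(frac, 1.0)))
    return cfg.lr * (cfg.min_lr_frac + (1.0 - cfg.min_lr_frac) * cos)


def _as_batches(pairs, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(len(pairs))
    for i in range(0, len(order), batch_size):
        chunk = [pairs[j] for j in order[i:i + batch_size]]
        noisy = np.stack([p.noisy for p in chunk]).astype(DTYPE)[:, None]
        clean = np.stack([p.clean for p in chunk]).astype(DTYPE)[:, None]
        yield noisy, clean


def train(model: GRRDB, train_pairs, cfg: TrainConfig, checkpoint_path=None,
          progress: bool = False):
    """Minimize MSE(model(noisy), clean) with Adam.

    Returns ``(best_state, loss_history)`` where ``best_state`` is the state
    dict of the epoch with the lowest mean training loss and
    ``loss_history`` has one mean-loss entry per epoch.  Deterministic given
    ``cfg.seed``.  A non-finite loss aborts with a diagnostic.
    """
    if len(train_pairs) == 0:
        raise ValueError("no training pairs")
    opt = Adam(model.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    history: list[float] = []
    best = (np.inf, model.state_dict())
    steps_per_epoch = int(np.ceil(len(train_pairs) / cfg.batch_size))
    total_steps = steps_per_epoch * cfg.epochs
    step = 0
    iterator = range(cfg.epochs)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="epochs")
    for epoch in iterator:
        losses = []
        for b, (noisy, clean) in enumerate(_as_batches(train_pairs, cfg.batch_size, rng)):
            step += 1
            opt.lr = _lr_at(step, cfg, total_steps)
            opt.zero_grad()
            out = model(Tensor(noisy))
            # train on the clipped output: evaluation (and any stored image)
            # lives in [0,1], so the loss should too; straight-through grad
            loss = F.mse_loss(F.clip01_ste(out), Tensor(clean))
            val = loss.item()
            if not np.isfinite(val):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {b} (lr={cfg.lr})")
            loss.backward()
            opt.step()
            losses.append(val)
        mean_loss = float(np.mean(losses))
        history.append(mean_loss)
        if mean_loss < best[0]:
            best = (mean_loss, model.state_dict())
        log.info("epoch %d/%d: mean loss %.3e", epoch + 1, cfg.epochs, mean_loss)
    model.load_state_dict(best[1])
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path)
    return best[1], history


def evaluate(model: GRRDB, test_pairs, L: float = 1.0,
             windowed: bool = True) -> metrics.MetricsReport:
    """Denoise each noisy test image and report per-level mean PSNR/SSIM."""
    if len(test_pairs) == 0:
        raise ValueError("no test pairs")
    triples = []
    for p in test_pairs:
        den = model.denoise(p.noisy)
        triples.append((p.clean, den, p.mold_level))
    return metrics.evaluate_set(triples, L=L, windowed=windowed)


def input_report(test_pairs, L: float = 1.0, windowed: bool = True) -> metrics.MetricsReport:
    """Noisy-vs-clean baseline metrics (what an identity denoiser scores)."""
    return metrics.evaluate_set([(p.clean, p.noisy, p.mold_level) for p in test_pairs],
                                L=L, windowed=windowed)


def _pairs_checksum(pairs) -> str:
    h = hashlib.sha256()
    for p in pairs:
        h.update(np.ascontiguousarray(p.clean).tobytes())
        h.update(np.ascontiguousarray(p.noisy).tobytes())
    return h.hexdigest()[:16]


def run_experiment(model_cfg: ModelConfig, train_cfg: TrainConfig,
                   n_per_level: int = 50, snr_db: float = 30.0,
                   phantom_cfg: phantom.PhantomConfig | None = None,
                   data_seed: int = 0, model_seed: int = 0, windowed_ssim: bool = True):
    """Generate phantoms, split 9:1, train, and evaluate.

    Returns a dict with the trained model, per-epoch losses, the test report
    and the noisy-input baseline report.
    """
    noise = phantom.NoiseSpec(kind="awgn_snr", snr_db=snr_db)
    pairs = phantom.generate_pairs(n_per_level, phantom_cfg, noise, seed=data_seed)
    tr_idx, te_idx = split_dataset(pairs, train_cfg.split, seed=train_cfg.seed)
    assert not set(tr_idx) & set(te_idx)
    train_pairs = [pairs[i] for i in tr_idx]
    test_pairs = [pairs[i] for i in te_idx]
    model = build_grrdb(model_cfg, seed=model_seed)
    _, history = train(model, train_pairs, train_cfg)
    report = evaluate(model, test_pairs, windowed=windowed_ssim)
    baseline = input_report(test_pairs, windowed=windowed_ssim)
    return {
        "model": model,
        "loss_history": history,
        "report": report,
        "input_report": baseline,
        "train_ids": [pairs[i].id for i in tr_idx],
        "test_ids": [pairs[i].id for i in te_idx],
        "data_checksum": _pairs_checksum(pairs),
    }


# ---------------------------------------------------------------------------
# graded-noise robustness and ablation
# ---------------------------------------------------------------------------

def noise_robustness(model_cfg: ModelConfig, train_cfg: TrainConfig,
                     levels_db=(20.0, 30.0, 40.0, 50.0), n_per_level: int = 10,
                     phantom_cfg: phantom.PhantomConfig | None = None,
                     data_seed: int = 0, train_models: bool = True,
                     windowed_ssim: bool = True) -> list[dict]:
    """Graded Gaussian-noise harness: one row per SNR level.

    Each row carries the noisy-input PSNR/SSIM at that level and, when
    ``train_models`` is on, the metrics of a model trained at that level
    (one model per level).
    """
    rows = []
    for level in levels_db:
        if train_models:
            res = run_experiment(model_cfg, train_cfg, n_per_level=n_per_level,
                                 snr_db=level, phantom_cfg=phantom_cfg,
                                 data_seed=data_seed, windowed_ssim=windowed_ssim)
            rep, base = res["report"], res["input_report"]
        else:
            noise = phantom.NoiseSpec(kind="awgn_snr", snr_db=level)
            pairs = phantom.generate_pairs(n_per_level, phantom_cfg, noise, seed=data_seed)
            base = input_report(pairs, windowed=windowed_ssim)
            rep = None
        levels = base.per_level.values()
        row = {
            "snr_db": level,
            "input_psnr_db": float(np.mean([s.psnr_db for s in levels])),
            "input_ssim": float(np.mean([s.ssim for s in base.per_level.values()])),
        }
        if rep is not None:
            row["model_psnr_db"] = float(np.mean([s.psnr_db for s in rep.per_level.values()]))
            row["model_ssim"] = float(np.mean([s.ssim for s in rep.per_level.values()]))
        rows.append(row)
    return rows


def ablate(spec: AblationSpec, model_cfg: ModelConfig, train_cfg: TrainConfig,
           n_per_level: int = 10, snr_db: float = 30.0,
           phantom_cfg: phantom.PhantomConfig | None = None,
           data_seed: int = 0, windowed_ssim: bool = True) -> list[dict]:
    """Train each architecture variant on identical data and seeds.

    Rows report per-variant parameter counts, mean test PSNR/SSIM, and the
    dataset checksum (identical across variants by construction).
    """
    rows = []
    for name in spec.variants:
        vcfg = variant_config(name, model_cfg)
        res = run_experiment(vcfg, train_cfg, n_per_level=n_per_level, snr_db=snr_db,
                             phantom_cfg=phantom_cfg, data_seed=data_seed,
                             windowed_ssim=windowed_ssim)
        rep = res["report"]
        rows.append({
            "variant": name,
            "n_parameters": res["model"].n_parameters(),
            "psnr_db": float(np.mean([s.psnr_db for s in rep.per_level.values()])),
            "ssim": float(np.mean([s.ssim for s in rep.per_level.values()])),
            "data_checksum": res["data_checksum"],
        })
    return rows
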