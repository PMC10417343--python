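# grrdb — dense-residual denoising for terahertz grain images

Terahertz (THz) reflectance imaging is used to grade mold contamination in
stored wheat: each kernel appears as a bright elliptical blob whose interior
texture degrades as mold consumes nutrients.  Source-power fluctuation and
detector noise corrupt these images and hurt downstream classification.

`grrdb` implements the **G-RRDB** denoising network — a residual-in-residual
dense block (RRDB) trunk preceded by three **Ghost-LKA** blocks (large-kernel
attention decomposed into depthwise 5×5, depthwise-dilated 7×7 (dilation 3)
and 1×1 convolutions, fused with a parameter-cheap ghost convolution) and
flanked by a residual branch of two **dual-attention blocks** (DAB) that fuse
spatial and channel attention through a sigmoid gate:

    LKA:   A = Conv1×1(DW-D-Conv7×7(DW-Conv5×5(F))),   out = A ⊙ F
    DAB:   out = W⊙s1 + Xout⊙(1−W) + W⊙s2 + Xout⊙(1−W),  W = σ(local+global)
    RRDB:  dense blocks with residuals scaled by β = 0.2

Training minimizes pixel MSE; quality is reported as PSNR
(`10·log10(L²/MSE)`, dB) and SSIM (11×11 Gaussian window, σ = 1.5,
k₁ = 0.01, k₂ = 0.03).

Because the real THz wheat data are confidential, the package ships a
synthetic **phantom** generator that reproduces the spatial statistics of
background-removed THz images — kernel-shaped radial blobs on an exact-zero
background, interior speckle and decay growing with mold level 0–3, and
calibrated additive Gaussian noise (target SNR in dB) or row-gain drift.
Everything — network, reverse-mode autodiff, Adam — runs on NumPy; no GPU
or deep-learning framework is required.

## Worked example

```python
import numpy as np
from grrdb import phantom, train_eval
from grrdb.gnet import desk_config

pcfg = phantom.PhantomConfig(canvas_h=64, canvas_w=64, n_kernels=3,
                             kernel_axis_range=(6.0, 11.0))
res = train_eval.run_experiment(
    desk_config(),                                  # 16-channel G-RRDB
    train_eval.desk_train_config(epochs=5, seed=0), # Adam lr 1e-3, batch 8
    n_per_level=50, snr_db=30.0, phantom_cfg=pcfg)  # 200 pairs, 9:1 split

inp = np.mean([s.psnr_db for s in res["input_report"].per_level.values()])
out = np.mean([s.psnr_db for s in res["report"].per_level.values()])
print(f"noisy input: {inp:.2f} dB   denoised: {out:.2f} dB   gain: {out-inp:+.2f} dB")
```

which prints (one CPU core, a few minutes):

```
noisy input: 47.98 dB   denoised: 50.94 dB   gain: +2.96 dB
```

The noisy-input PSNR is high because phantoms are mostly exact-zero
background while the noise is calibrated against the mean signal power; the
gain line is the meaningful number — the trained network removes a
substantial fraction of the injected noise energy on held-out images.

The same experiment is available from the shell:

```sh
grrdb generate --out data/ --n-per-level 50 --snr-db 30 --seed 0 --size 64
grrdb train --data data/ --out run/ --epochs 5
grrdb denoise --checkpoint run/model.ckpt --in data/m2_0003_noisy.png --out den.png
grrdb describe --desk
```

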