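# Methods

## Problem setting

Terahertz (THz) reflectance imaging of grain produces single-channel
intensity maps in which each kernel appears as a bright, roughly elliptical
blob on a dark (background-removed) field.  Source-power fluctuation and
detector noise degrade these images, which in turn degrades downstream
classification of mold severity.  This package implements a convolutional
denoiser, G-RRDB, for such images, together with the evaluation metrics
(PSNR/SSIM), a synthetic phantom benchmark, and a training/ablation harness.

Because real THz cubes of moldy wheat are not publicly available, all
experiments here run on synthetic phantoms (below).  Results on phantoms
demonstrate that the architecture, loss, metrics and training loop behave
correctly; they do not certify performance on real THz data, whose spectral
statistics, spatially correlated noise and lack of a noise-free reference
the phantom model does not attempt to reproduce.

## Architecture

The network maps an image `x ∈ [0,1]^{H×W}` to a same-size denoised
estimate.  All convolutions are stride-1 with zero-padded "same" semantics,
so every block preserves spatial shape.

* **Head**: 3×3 conv, 1 → C channels (C = 64 by default, 16 in the desk
  preset).
* **Ghost-LKA × 3**: large-kernel attention (LKA) followed by a ghost
  convolution, with a residual sum.  LKA decomposes a large kernel into a
  depthwise 5×5 conv, a depthwise 7×7 conv with dilation 3 (≈ 21×21
  receptive field), and a 1×1 conv; its output multiplicatively gates the
  block input (`out = A ⊙ x`).  The ghost convolution produces `C/r`
  "intrinsic" maps by an ordinary 3×3 conv and derives the remaining
  `C·(r−1)/r` maps by cheap depthwise 3×3 operations (r = 2 by default),
  roughly halving the parameters of the equivalent dense conv.
* **RRDB trunk × 5**: residual-in-residual dense blocks.  Each dense block
  runs 5 convs whose inputs concatenate the block input and all previous
  outputs (growth C/2, LReLU slope 0.2 after all but the last), and adds the
  last conv output back scaled by β = 0.2.  Each RRDB chains 3 dense blocks
  and wraps them in an outer residual, again weighted by β.
* **DAB branch × 2 (serial)**: a dual-attention block computes a spatial
  attention map s1 (channel mean/max → 7×7 conv → sigmoid gate), a channel
  attention map s2 (global average+max pooling → shared bottleneck C → C/4 →
  C → sigmoid gates), fuses them (`Xa = s1 + s2`), derives a combined gate
  `W = σ(local 3×3 conv(Xa) + global pooled bottleneck(Xa))`, and outputs
  `W⊙s1 + Xout⊙(1−W) + W⊙s2 + Xout⊙(1−W)` where `Xout` is a plain
  conv+ReLU feature branch.  The two DABs form a residual branch over the
  trunk output (`T + DAB(DAB(T))`).
* **Tail**: two 3×3 conv+ReLU layers and a 1×1 conv back to one channel;
  the input image is added to the result (global skip), so the network
  predicts a residual correction.

### Design choices where the design was open

* **Outer RRDB residual.** Each dense block is `x + β·F(x)`.  For the outer
  combination we use `x + β·(chain(x) − x)`, i.e. the residual of the whole
  chain, so that a block with all-zero weights is an *exact* identity — the
  property the rest of the initialization strategy builds on.  The
  ESRGAN-style literal form `x + β·chain(x)` (which maps identity chains to
  `1.2·x`) is available via `rrdb_literal_residual`.
* **DAB gate combination.** The gated fusion uses complementary weighting
  `Xout⊙(1−W)` in both feature terms; a variant reading with one `Xout⊙W`
  term is available via `eq3_literal`.  The limits are easy to read off:
  `W≡1` passes the fused attention maps, `W≡0` passes `2·Xout`.
* **DAB is stride-1.** The branch must merge with a full-resolution trunk,
  so "down-sampling" is interpreted as channel-preserving feature
  extraction, not spatial reduction.
* **LKA dilation 3** with a 7×7 dilated depthwise kernel — the canonical
  large-kernel decomposition from the visual-attention literature.
* **Initialization.** Kaiming fan-in scaling everywhere, except the final
  1×1 conv, which is zero-initialized: with the global skip the fresh
  network is exactly the identity, so training starts from the noisy input's
  own PSNR and cannot initially corrupt the image.  A consequence worth
  knowing: at exact initialization the zero output conv blocks gradient flow
  into the trunk for the very first optimizer step; the step updates the
  output conv (and biases), after which gradients flow everywhere.

## Loss and metrics

Training minimizes the mean squared error over all pixels of a batch,
`L = (1/N) Σ (y_i − ŷ_i)²`.

* **PSNR** `= 10·log10(L²/MSE)` dB with dynamic range L (1.0 for unit-scaled
  floats, 255/65535 when metrics are taken on stored integer images).
  Identical images give a documented `+inf` sentinel.
* **SSIM** uses local statistics under an 11×11 Gaussian window (σ = 1.5,
  the standard reference convention), constants `c1 = (0.01·L)²`,
  `c2 = (0.03·L)²`, population covariance, and crops the half-window border
  before averaging the similarity map.  `windowed=False` computes the same
  formula from whole-image statistics (the windowing convention is not
  universal; both are provided).

## Synthetic phantoms

`grrdb.phantom` emulates the *spatial* statistics of background-removed THz
wheat images:

* Rotated ellipses (semi-axes drawn from `kernel_axis_range`, elongated)
  with a smooth radial intensity profile `peak·(1−r²)^0.6`, placed by
  rejection sampling with a 1-pixel guard band (≤ 50 retries per kernel;
  on failure the image carries fewer kernels and a warning is logged).
  Background is exactly zero.
* Mold level m ∈ {0,1,2,3} (normal / slight / moderate / serious) maps to
  interior texture: multiplicative speckle of amplitude `0.05 + 0.1·m`
  (smoothed zero-mean field) and a suppressed-intensity sub-ellipse covering
  `0.15·m` of the kernel area at 0.45× intensity — mean interior intensity
  therefore decreases with mold level, mirroring the nutrient-loss contrast
  visible in real data.
* Noise models: `awgn_snr` adds white Gaussian noise with variance
  `mean(clean²)/10^(SNR/10)` — signal power is the mean squared intensity
  of the whole image, a convention chosen because it is directly testable
  (empirical SNR within 0.2 dB of target on average); `awgn_sigma` adds
  fixed-σ noise; `power_drift` multiplies each row by `1 + a·g(row)` with
  `g` a smoothed random walk normalized into [−1,1], emulating source-power
  drift across a raster scan.  Images are clipped to [0,1] *after* noise;
  empirical SNR is measured pre-clip.
* Determinism: sample i of a dataset uses sub-seed `master_seed + i` (and
  an offset stream for its noise), so generation is a pure function of
  (config, master seed).

Note that on these phantoms the PSNR of a noisy image against its clean
reference is high (≈ 47 dB at 30 dB SNR with unit dynamic range) because
most of the canvas is exact-zero background; PSNR is computed against the
full dynamic range while the noise power is calibrated to the (small) mean
signal power.

## Training protocol

Adam with initial learning rate 1e-3, batch size 8, MSE loss, datasets split
9:1 into train/test stratified by mold level (exact partition, deterministic
per seed; a level with fewer than two samples stays whole in train with a
warning).  The learning rate ramps linearly to its initial value over the
first 30 optimizer steps and is constant afterwards.  The warmup exists
because of a specific interaction between Adam and the identity
initialization: Adam's bias-corrected update takes ≈ lr-sized steps on
*every* parameter from the first batch regardless of gradient magnitude,
which throws the carefully balanced identity network to a training loss
orders of magnitude above the noise floor before learning claws it back —
measurably wasting a large share of a short CPU-scale run.  Thirty steps is
about one desk-scale epoch and a negligible fraction of the full-scale
protocol.  After the warmup the rate follows a cosine decay to 5 % of its
initial value over the remaining steps ("initial learning rate" names the
peak; the decay lets the final steps settle instead of bouncing in an
lr-sized neighbourhood of the optimum).

The loss is computed on the network output *clipped to [0,1]*, with the
gradient passed straight through the clip.  Evaluation — like any stored
image — lives in [0,1], so the training objective should too; concretely,
clipping lets the network drive background predictions to exact zero (the
clean background value) by pushing them negative, instead of chasing the
unclipped noise realization.  The checkpoint kept is the epoch with the
lowest mean training loss; test identifiers never enter a training batch
and both id sets are returned for auditing.  The full-scale protocol uses 70 epochs and C = 64;
the desk-scale preset used throughout the test suite uses C = 16, 64×64
phantoms and 5 epochs, sized so a complete scaled experiment (200 paired
phantoms) runs in minutes on one CPU core.

For the graded-noise harness a separate model is trained per noise level
(20/30/40/50 dB) by default; `train_models=False` reports only the
noisy-input metrics, whose monotone increase with SNR is asserted in tests.

## Numerical engine

The network runs on a small reverse-mode autodiff core (`grrdb.nn`) written
on NumPy: float32 tensors, iterative topological-order backpropagation,
convolutions evaluated as one stacked GEMM over kernel taps with shifted
accumulation (and the matching transposed forms for the input/weight
gradients), depthwise and dilated convolutions as per-tap scaled shifts.
Gradients of every op are verified against central finite differences in the
test suite, and forward paths against naive loop oracles.  Adam follows the
standard bias-corrected update with ε = 1e-8.

## Tiled inference

Images larger than one tile (256 px default) are denoised tile-by-tile with
16-px overlap and separable linear feathering in the overlap.  Blending is
exact for shift-invariant outputs away from tile borders; within a
receptive-field distance of a tile edge the padded context differs from the
full image, so seams agree only approximately — the CLI uses margins large
enough that the discrepancy is invisible at 16-bit quantization for the
default configuration.

## Known limitations

* Phantoms do not model THz spectral structure, speckle correlation between
  frequency layers, or scanning artifacts other than row-gain drift.
* The training protocol at desk scale (5 epochs, ~100 Adam steps) is far
  from convergence; it demonstrates learning (a multi-dB PSNR gain over the
  noisy input), not the architecture's asymptotic performance.
* CPU-only: no GPU path, no mixed precision; throughput is bounded by
  single-thread BLAS.
* Comparison denoisers (BM3D, DnCNN, ADNet, CBDNet) are published tools and
  are not reimplemented here; the built-in ablation compares the RRDB
  baseline, baseline+DAB, and full G-RRDB.
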