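# Methods

`wavecal` implements a hybrid learned codec for single-channel 2-D images in
the style of CT/MRI slices.  This note records the model, the choices made
where the design was genuinely open, the numerical conventions, and what the
synthetic phantoms do and do not demonstrate.

## Pipeline

Compression of an image `I ∈ [0,1]^{m×n}`:

1. **Wavelet analysis.** A level-1 2-D DWT splits `I` into
   `{LL, LH, HL, HH}` subbands at half resolution.  Default wavelet is
   orthonormal Haar; any pywt wavelet is accepted.  Orientation convention:
   `LH` is the high-pass across rows (horizontal edges / row differences),
   `HL` across columns, `HH` diagonal.  The default boundary mode is
   `periodization`, which makes orthonormal transforms exactly orthogonal:
   subband shapes are `⌈m/2^k⌉×⌈n/2^k⌉`, coefficient energy equals image
   energy to 1e-9 relative, and reconstruction is exact to float64
   round-off.  (`symmetric` and the other pywt modes are available but give
   up exact energy conservation.)
2. **Band normalization.** Each band is mapped affinely into `[0,1]`:
   `LL/2` and `(d+2)/4` for the detail bands.  These bounds are exact for
   Haar on `[0,1]` inputs and conservative for other short wavelets; any
   overshoot is clipped.
3. **Cross-attention (CAL).** Feature maps are tokenized per spatial
   position (channels are the token features) and linearly embedded to
   `embed_dim` (default 64, 8 heads).  Queries come from the LL channel,
   keys/values from the stacked `{LH, HL, HH}` channels — "given the local
   anatomy, which details matter".  The attended output is projected back
   to 3 channels and added to the input (residual), so the block emphasizes
   or suppresses details rather than replacing them, and is the identity at
   zero-initialized value/output paths.
4. **VAE.** The LL channel concatenated with the reweighted detail channels
   (4 channels) feeds a convolutional encoder: per layer 3×3 convolution →
   ReLU → batch-norm → 2×2 max-pool (default four layers, widths
   32/64/128/128), then a dense hidden layer with dropout 0.3 and two dense
   heads for the latent mean `μ` and log-variance.  The decoder mirrors the
   encoder with transposed convolutions (4×4, stride 2) and a final sigmoid.
   Additive skip connections between matching resolutions exist behind a
   flag but default **off** in codec mode: true skips bypass the latent
   bottleneck, which is incompatible with compression.
5. **Quantization + entropy coding.** At inference the latent code is the
   posterior mean `μ` (no sampling).  A uniform mid-tread quantizer
   (`round half away from zero`, symmetric clip at ±127 → 255-letter
   alphabet) produces symbols coded by an adaptive order-0 range coder
   (32-bit renormalizing, carry-propagating; counts start at 1, +8 per
   observed symbol, halved when the total passes 2^16).  The increment
   balances fast adaptation on low-entropy streams (constant stream of 10⁴
   symbols: ≈0.04 bits/symbol) against negligible overhead on
   incompressible ones (uniform 256-letter stream: ≈1.3 % above 8
   bits/symbol).
6. **Container.** A little-endian header (`WCAL`, version, shape, wavelet
   id, levels, qstep as float32, clip range, 8-byte model hash, symbol
   count, CRC-32 of the payload) precedes the payload.  `bpp` counts header
   plus payload bits over `m·n`.  Quantization uses the float32-rounded
   step so encoder and decoder are bit-identical.  Corruption is detected
   by the CRC; mismatched models are refused via the hash (a truncated
   blake2b over config and weights).
7. **Decompression** reverses each stage; an optional trained 3×3 spatial
   filter refines the output.

The neural codec path operates on a single decomposition level (the level
the pipeline equations describe); the wavelet module itself supports
arbitrary depths for analysis use.

## Training

Loss: `L = λ1·L_recon + λ2·L_perceptual + λ3·KL` with `L_recon` the
pixelwise MSE of the normalized subband features (a binary-cross-entropy
reconstruction mode is selectable), `KL` the closed-form divergence of the
diagonal Gaussian posterior from `N(0, I)`, and `L_perceptual` an L2
distance in the feature space of a small *frozen, seeded, untrained*
two-layer convolutional extractor.  Random convolutional features preserve
feature-space geometry well enough to serve the perceptual role without
any pretrained weights; λ2 defaults to 0.01, λ3 to 1e-3.  Optimizer is
Adam (β₁ 0.9, β₂ 0.999), learning rate 1e-4 by default (2e-4 is the
documented alternative), batch 32, up to 150 epochs, Xavier-normal
initialization, dropout 0.3 after the dense hidden layer, early stopping
on validation loss with patience 10 (best checkpoint kept; first
occurrence wins ties).  Data splits are 70/15/15 by a seeded shuffle with
cumulative-boundary rounding (remainder goes to the training set); an
optional k-fold driver repeats training per fold.  Training samples the
latent via the reparameterization `z = μ + exp(logvar/2)·ε`; quantization
is bypassed during training and applied post hoc (quantization-aware
training is deliberately out of scope).

All randomness flows from integer seeds through named numpy generators;
training is single-threaded and bit-reproducible: the same config and seed
give byte-identical checkpoints.

## Scaled-down fixture experiments

Tests and the acceptance script exercise the full pipeline at desk scale:
200 phantoms of 32×32, a two-layer encoder (widths 16/32), latent 64,
dense hidden 128, 4 heads, embedding 16, 30 epochs, batch 8, learning
rate 1e-2 with a reconstruction-dominated loss (λ2 = 0, λ3 = 1e-5), no
dropout.  The higher learning rate and small batch compensate for the
short schedule (~500 updates total — at the full-scale 1e-4 the network
would remain essentially at initialization), and the fixture model is
sized to what 30 epochs can actually fit.  These problem sizes were
chosen so the full suite runs on one CPU core in minutes; they measure
that the machinery trains and compresses, not clinical-grade quality —
the fixture codec lands around 19–20 dB PSNR at ≈0.7 bpp on held-out
phantoms, roughly 9 dB above the constant-mean baseline.

## Synthetic phantoms

Each phantom is a constant background (0.10) plus one dominant rim ellipse
producing a clean intensity step of `edge_contrast` (default 0.5), a
handful of rotated graded interior ellipses, small Gaussian-profile bright
nodules (amplitude 0.3, σ 0.8–2.5 px), and i.i.d. Gaussian noise
(default σ 0.02), clipped to `[0,1]` — the four ingredients (smooth
regions, bone-like step edges, lesions, noise) that drive wavelet subband
content in real scans.  Phantoms are deterministic functions of their spec
including the seed.  They do **not** reproduce the intensity statistics,
texture, or partial-volume effects of real CT/MRI; passing fixture gates
demonstrates mechanical correctness and trainability, not diagnostic
fidelity.

## Metrics conventions

All quality metrics operate on the 0..255 scale (`[0,1]` images are scaled
by 255 first): PSNR hard-codes peak 255, and SSIM's default constants
`C1 = (0.01·255)²`, `C2 = (0.03·255)²` assume the same range.  SSIM uses
the community-standard 11×11 Gaussian window (σ 1.5) with weighted local
moments, averaged over windows fully inside the image.  PSNR of identical
images is reported as `+inf`, never NaN.  NCC is the *uncentered* cosine
similarity, which equals Pearson correlation only for zero-mean images —
the distinction is asserted in the tests.  Published benchmark rows that
pair MSE with PSNR values inconsistent with the 255-scale formula are
treated as reported data; only their average row is recomputed.

## Pixel predictors

Two small feedforward regressors (hidden stack 20→18→5, tanh, linear
output) forecast pixels from 8-pixel contexts: the 3×3 surround predicting
the centre (1 output), and 8 consecutive in-row pixels predicting the next
two (2 outputs).  The leading "20" of the stack is read as the first
hidden width, so output widths 1 and 2 match the predicted pixel counts.
Training is full-batch Adam (seeded), quality is the Pearson R between
held-out predictions and targets with both output columns pooled; zero-
variance targets raise a flagged error.  The subsystem is standalone
(`wavecal predict-pixels`): it is not wired into the default bitstream, as
no rate-pipeline integration is specified for it.

## Spatial filter

A single 3×3 kernel + bias, applied with reflect padding and clipped to
`[0,1]`.  Training minimizes `w_mse·MSE + w_ssim·(1−SSIM)` (metrics
module, 0..255 scale) with Adam from an identity-plus-noise
initialization; the MSE gradient is analytic (clipping treated as a hard
gate), the SSIM term falls back to central differences over the 10
parameters.  The best iterate is returned, so the trained filter is never
worse than its start; identical training pairs are a no-op.

## Known limitations

* Attention is dense over per-pixel tokens: cost grows with the fourth
  power of image side length.  Fine at fixture sizes; large images would
  need patch tokenization (a config hook exists in spirit but is not the
  default).
* The codec's dense layers tie a trained model to one image size.
* Entropy coding is order-0; no hyperprior or context model.
* The quantizer clips latents at ±clip_range·step; with KL-regularized
  latents this is never active in practice, but pathological inputs could
  saturate.
* Metrics treat images as full-reference pairs; no perceptual metrics
  beyond SSIM.
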