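# wavecal

Hybrid learned compression for single-channel 2-D medical-style images
(CT/MRI slices and look-alikes), combining classical multi-resolution
analysis with attention-driven feature weighting and variational latent
coding.  It is aimed at people studying learned codecs for grayscale
clinical imagery who need a fully seeded, CPU-sized, end-to-end testable
reference implementation — no datasets, pretrained weights, or GPUs
required.

## The model

For an image `I ∈ [0,1]^{m×n}` the encoder computes

```
{LL, LH, HL, HH} = DWT(I)                         (level-1 wavelet analysis)
Attention(Q,K,V) = softmax(QKᵀ/√d_k)·V            (scaled dot-product)
MultiHead(Q,K,V) = Concat(head_1,…,head_h)·W_o    (h = 8, embed dim 64)
```

with queries taken from LL (structure) and keys/values from the detail
subbands, so the cross-attention block re-weights high-frequency content
by its structural relevance.  The reweighted features feed a convolutional
VAE (3×3 convs + ReLU + batch-norm + 2×2 max-pool; Gaussian latent prior;
mirrored transposed-convolution decoder) trained with

```
L = λ₁·L_MSE + λ₂·L_Perceptual + λ₃·KL
```

The latent mean is uniformly quantized and compressed by an adaptive
order-0 arithmetic (range) coder into a small self-describing container.
Reconstruction quality is reported as MSE, `PSNR = 20·log₁₀(255/√MSE)`,
SSIM (Gaussian 11×11 window, σ = 1.5, C₁ = (0.01·255)², C₂ = (0.03·255)²)
and the uncentered correlation `NCC = ΣW·W̄ / (√ΣW²·√ΣW̄²)`, plus bits per
pixel counted over the full container.  A trainable 3×3 spatial filter
(learned by backpropagation against an MSE/SSIM objective) can refine the
decoded image, and a standalone pixel-estimation module predicts
intensities from 8-pixel contexts (3×3 surround → centre, or 8-in-a-row →
next two) with small tanh networks.

Because clinical archives cannot ship with a library, the package includes
a seeded phantom generator (Shepp-Logan-flavoured ellipses, bright
nodules, Gaussian noise) that exercises every stage.

## Worked example

A desk-scale training config (`desk.yaml`) that fits 32×32 phantoms in a
couple of minutes on one CPU core:

```yaml
codec:
  image_hw: [32, 32]
  channels: [16, 32]
  latent_dim: 64
  dense_hidden: 128
  heads: 4
  embed_dim: 16
  dropout: 0.0
train:
  learning_rate: 0.01
  batch_size: 8
  epochs: 20
  loss_weights: {lambda1: 1.0, lambda2: 0.0, lambda3: 1.0e-05}
```

```
$ wavecal simulate --n 60 --size 32 --seed 7 --out-dir scratch/phantoms
wrote 60 phantoms to scratch/phantoms

$ wavecal train scratch/phantoms --model scratch/model.npz --config desk.yaml --seed 7
trained on 42 images; best epoch 14; val recon MSE 2.120e-02 -> 3.031e-03; saved scratch/model.npz

$ wavecal compress scratch/phantoms/phantom_0000.png --model scratch/model.npz --out scratch/p0.wcal
scratch/phantoms/phantom_0000.png -> scratch/p0.wcal: 0.680 bpp

$ wavecal decompress scratch/p0.wcal --model scratch/model.npz --out scratch/p0_rec.png
scratch/p0.wcal -> scratch/p0_rec.png

$ wavecal evaluate scratch/phantoms --model scratch/model.npz --out scratch/report.csv
60 images: PSNR 18.54 dB, SSIM 0.4088, 0.670 bpp -> scratch/report.csv
```

Reading the numbers: 20 epochs cut the validation reconstruction error of
the subband features by ~7× (2.12e-2 → 3.03e-3); the codec then spends
≈0.68 bits per pixel (a 64-long quantized latent plus a 26-byte header for
a 32×32 image) and reconstructs phantoms around 18.5 dB PSNR — far from
clinical quality, but produced by the complete DWT → attention → VAE →
entropy-coding → inverse pipeline at toy scale.  `wavecal rd-curve` sweeps
the quantization step to trade bpp against PSNR/SSIM, and
`wavecal predict-pixels IMG --window square3x3` trains the
neighbour-context regressor and prints its held-out correlation R.

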