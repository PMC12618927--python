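"""Convolutional variational autoencoder over attention-weighted subband
features.

Encoder: four (configurable) 3x3 convolution blocks, each convolution ->
ReLU -> batch-norm -> 2x2 max-pool, then a dense hidden layer (with
dropout) feeding two fully connected heads for the latent mean and
log-variance.  The latent code is regularized toward a standard-normal
prior via the closed-form KL term.  Decoder mirrors the encoder with
transposed convolutions and a final sigmoid so outputs live in [0, 1];
additive skip connections between matching resolutions are available but
default off in codec mode (they would bypass the latent bottleneck).

The composite training objective is

    L = lambda1 * L_recon + lambda2 * L_perceptual + lambda3 * KL

with L_recon either pixelwise MSE (default) or binary cross-entropy (the
alternative reconstruction mode), and L_perceptual an L2 distance in the
feature space of a small frozen seeded convolutional extractor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import (ConfigurationError, NumericalError, StructuralError,
                     WavecalError)
from .nn import Tensor, as_tensor

__all__ = [
    "EncoderSpec",
    "LatentDistribution",
    "LossWeights",
    "LossBreakdown",
    "VAE",
    "PerceptualFeatures",
    "reparameterize",
    "kl_gaussian",
    "composite_loss",
]


@dataclass(frozen=True)
class EncoderSpec:
    in_channels: int = 4
    input_hw: tuple[int, int] = (16, 16)
    n_conv_layers: int = 4
    channels: tuple[int, ...] = (32, 64, 128, 128)
    kernel: int = 3
    latent_dim: int = 64
    dense_hidden: int = 128
    dropout: float = 0.3
    skip_connections: bool = False

    def __post_init__(self):
        if len(self.channels) != self.n_conv_layers:
            raise ConfigurationError("channels must list one width per layer")
        h, w = self.input_hw
        d = 2**self.n_conv_layers
        if h % d or w % d:
            raise ConfigurationError(
                f"input {h}x{w} not divisible by 2^{self.n_conv_layers}"
            )
        if self.latent_dim < 1 or self.dense_hidden < 1:
            raise ConfigurationError("latent_dim/dense_hidden must be >= 1")


@dataclass
class LatentDistribution:
    """Diagonal Gaussian posterior: mean, log-variance, optional sample."""

    mu: object
    logvar: object
    z: object | None = None

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        mu = self.mu.data if isinstance(self.mu, Tensor) else np.asarray(self.mu, float)
        lv = (self.logvar.data if isinstance(self.logvar, Tensor)
              else np.asarray(self.logvar, float))
        return mu, lv


@dataclass(frozen=True)
class LossWeights:
    lambda1: float = 1.0    # reconstruction
    lambda2: float = 0.01   # perceptual
    lambda3: float = 1e-3   # KL

    def __post_init__(self):
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ConfigurationError("loss weights must be non-negative")
        if self.lambda1 == self.lambda2 == self.lambda3 == 0:
            raise ConfigurationError("at least one loss weight must be positive")


@dataclass
class LossBreakdown:
    total: object
    recon: object
    perceptual: object
    kl: object

    def as_floats(self) -> "LossBreakdown":
        def f(x):
            return float(x.data) if isinstance(x, Tensor) else float(x)

        return LossBreakdown(f(self.total), f(self.recon),
                             f(self.perceptual), f(self.kl))


class VAE(nn.Module):
    def __init__(self, spec: EncoderSpec, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.spec = spec
        pad = spec.kernel // 2
        self.enc_convs = []
        self.enc_bns = []
        c_in = spec.in_channels
        for c_out in spec.channels:
            self.enc_convs.append(nn.Conv2d(c_in, c_out, spec.kernel, rng,
                                            padding=pad))
            self.enc_bns.append(nn.BatchNorm2d(c_out))
            c_in = c_out
        h, w = spec.input_hw
        self.bottom_hw = (h // 2**spec.n_conv_layers, w // 2**spec.n_conv_layers)
        flat = spec.channels[-1] * self.bottom_hw[0] * self.bottom_hw[1]
        self.fc_hidden = nn.Linear(flat, spec.dense_hidden, rng)
        self.drop = nn.Dropout(spec.dropout, np.random.default_rng(rng.integers(2**31)))
        self.fc_mu = nn.Linear(spec.dense_hidden, spec.latent_dim, rng)
        self.fc_logvar = nn.Linear(spec.dense_hidden, spec.latent_dim, rng)

        self.fc_dec = nn.Linear(spec.latent_dim, flat, rng)
        self.dec_convs = []
        rev = list(spec.channels[::-1])
        outs = rev[1:] + [spec.in_channels]
        for c_i, c_o in zip(rev, outs):
            self.dec_convs.append(nn.ConvTranspose2d(c_i, c_o, 4, rng,
                                                     stride=2, padding=1))

    # -- halves ---------------------------------------------------------------
    def encode(self, x) -> LatentDistribution:
        """Posterior parameters for features x (N,C,H,W) or (C,H,W)."""
        x = as_tensor(x)
        squeeze = x.ndim == 3
        if squeeze:
            x = x.reshape(1, *x.shape)
        if x.shape[1] != self.spec.in_channels or tuple(x.shape[2:]) != self.spec.input_hw:
            raise StructuralError(
                f"expected {self.spec.in_channels}x{self.spec.input_hw} input, "
                f"got {x.shape[1:]}"
            )
        self._enc_feats = []
        for i, (conv, bn) in enumerate(zip(self.enc_convs, self.enc_bns)):
            x = bn(conv(x).relu())
            if not np.all(np.isfinite(x.data)):
                raise NumericalError(f"non-finite activations in encoder layer {i}")
            self._enc_feats.append(x)
            x = nn.maxpool2x2(x)
        flat = x.reshape(x.shape[0], -1)
        hid = self.drop(self.fc_hidden(flat).relu())
        mu, logvar = self.fc_mu(hid), self.fc_logvar(hid)
        if squeeze:
            mu = mu.reshape(-1)
            logvar = logvar.reshape(-1)
        return LatentDistribution(mu=mu, logvar=logvar)

    def decode(self, z):
        z = as_tensor(z)
        squeeze = z.ndim == 1
        if squeeze:
            z = z.reshape(1, -1)
        if z.shape[-1] != self.spec.latent_dim:
            raise StructuralError(
                f"latent length {z.shape[-1]} != latent_dim {self.spec.latent_dim}"
            )
        n = z.shape[0]
        c = self.spec.channels[-1]
        x = self.fc_dec(z).relu().reshape(n, c, *self.bottom_hw)
        n_up = len(self.dec_convs)
        for i, deconv in enumerate(self.dec_convs):
            x = deconv(x)
            if i < n_up - 1:
                if self.spec.skip_connections and hasattr(self, "_enc_feats"):
                    skip = self._enc_feats[n_up - 2 - i]
                    if skip.shape == x.shape:
                        x = x + skip
                x = x.relu()
        out = x.sigmoid()
        return out.reshape(*out.shape[1:]) if squeeze else out

    def forward(self, x, rng: np.random.Generator | None = None):
        dist = self.encode(x)
        if self.training and rng is not None:
            z = reparameterize(dist, rng)
        else:
            z = dist.mu  # deterministic code at inference
        dist.z = z
        return self.decode(z), dist


def reparameterize(dist: LatentDistribution, rng) -> object:
    """z = mu + exp(logvar/2) * eps, eps ~ N(0, I) from the seeded generator.

    ``rng`` may be a Generator or an integer seed.  Differentiable in mu and
    logvar when they are Tensors.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mu_a, lv_a = dist.arrays()
    if not (np.all(np.isfinite(mu_a)) and np.all(np.isfinite(lv_a))):
        raise NumericalError("non-finite latent parameters")
    eps = rng.standard_normal(mu_a.shape)
    if isinstance(dist.mu, Tensor):
        return dist.mu + (as_tensor(dist.logvar) * 0.5).exp() * Tensor(eps)
    return mu_a + np.exp(lv_a / 2.0) * eps


def _kl_tensor(mu: Tensor, logvar: Tensor) -> Tensor:
    """0.5 * sum(mu^2 + sigma^2 - 1 - log sigma^2), batch-averaged if 2-D."""
    per = (mu**2 + logvar.exp() - 1.0 - logvar) * 0.5
    if per.ndim == 2:
        return per.sum(axis=1).mean()
    return per.sum()


def kl_gaussian(dist: LatentDistribution) -> float:
    """Closed-form KL(q(z|x) || N(0, I)); non-negative, zero iff mu=logvar=0.
    For batched (N, D) inputs the per-image KLs are averaged."""
    mu, lv = dist.arrays()
    return float(_kl_tensor(Tensor(mu), Tensor(lv)).data)


_perceptual_cache: dict[int, "PerceptualFeatures"] = {}


class PerceptualFeatures(nn.Module):
    """Small frozen convolutional feature extractor for the perceptual term.

    Two seeded 3x3 conv + ReLU layers with fixed (untrained) weights: random
    projections preserve feature-space geometry well enough to act as a
    stand-in for learned perceptual features, and need no external weights.
    """

    SEED = 814523

    def __init__(self, in_channels: int):
        super().__init__()
        rng = np.random.default_rng(self.SEED + in_channels)
        self.c1 = nn.Conv2d(in_channels, 8, 3, rng, padding=1)
        self.c2 = nn.Conv2d(8, 8, 3, rng, padding=1)
        for p in self.parameters():
            p.requires_grad = False  # frozen

    def forward(self, x):
        return self.c2(self.c1(x).relu()).relu()


def _perceptual(in_channels: int) -> PerceptualFeatures:
    if in_channels not in _perceptual_cache:
        _perceptual_cache[in_channels] = PerceptualFeatures(in_channels)
    return _perceptual_cache[in_channels]


def composite_loss(recon, target, dist: LatentDistribution | None,
                   weights: LossWeights = LossWeights(),
                   mode: str = "mse") -> LossBreakdown:
    """Weighted training objective; ``mode`` is ``"mse"`` (MSE + perceptual +
    KL) or ``"bce"`` (binary cross-entropy + KL).  Returns Tensor-valued
    components when inputs are Tensors (use ``.as_floats()`` to report)."""
    to_numpy = not (isinstance(recon, Tensor) or isinstance(target, Tensor))
    recon, target = as_tensor(recon), as_tensor(target)
    if recon.shape != target.shape:
        raise StructuralError("recon/target shape mismatch")
    if mode not in ("mse", "bce"):
        raise ConfigurationError(f"unknown loss mode {mode!r}")

    if mode == "mse":
        rec = ((recon - target) ** 2).mean()
    else:
        if (recon.data.min() < 0 or recon.data.max() > 1
                or target.data.min() < 0 or target.data.max() > 1):
            raise WavecalError("BCE requires values in [0, 1]")
        eps = 1e-7
        r = recon * (1 - 2 * eps) + eps
        rec = -(target * r.log() + (1.0 - target) * (1.0 - r).log()).mean()

    if mode == "mse" and weights.lambda2 > 0:
        r4 = recon if recon.ndim == 4 else recon.reshape(1, 1, *recon.shape[-2:])
        t4 = target if target.ndim == 4 else target.reshape(1, 1, *target.shape[-2:])
        fx = _perceptual(r4.shape[1])
        perc = ((fx(r4) - fx(t4)) ** 2).mean()
    else:
        perc = Tensor(0.0)

    if dist is not None and weights.lambda3 > 0:
        kl = _kl_tensor(as_tensor(dist.mu), as_tensor(dist.logvar))
    else:
        kl = Tensor(0.0)

    total = weights.lambda1 * rec + weights.lambda2 * perc + weights.lambda3 * kl
    out = LossBreakdown(total=total, recon=rec, perceptual=perc, kl=kl)
    return out.as_floats() if to_numpy else out
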