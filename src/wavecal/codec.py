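"""End-to-end codec: subband features -> cross-attention -> VAE latents ->
quantization -> adaptive entropy coding -> bitstream container, and back.

Compression pipeline (one decomposition level):

1. level-1 DWT of the [0,1] image -> {LL, LH, HL, HH} at half resolution;
2. affine normalization of each band into [0,1] (LL/2; details (d+2)/4 —
   bounds exact for Haar, conservative for other short orthonormal
   wavelets);
3. a cross-attention (CAL) block reweights the three detail channels
   against LL queries; the LL channel plus reweighted details (4 channels)
   feed the VAE encoder;
4. at inference the latent code is the posterior mean mu (no sampling),
   uniformly quantized and range-coded into the payload of a small
   self-describing container.

Decompression reverses each stage and optionally applies a trained 3x3
spatial refinement filter.  Inference is fully deterministic: the same
(image, model, qstep) always yields byte-identical bitstreams.

Training minimizes the composite VAE loss on the normalized subband
features of a 70/15/15 split with Adam, batch training, dropout, and
early stopping on validation loss (best checkpoint kept, first occurrence
on ties).  Quantization is bypassed during training; it is applied post
hoc, which keeps the VAE objective smooth.
"""

from __future__ import annotations

import hashlib
import json
import struct
import time
import zlib
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import nn
from .attention import CALBlock, MultiHeadConfig
from .entropy import (QuantizerConfig, SymbolStream, decode_symbols,
                      dequantize, encode_symbols, quantize)
from .errors import (ConfigurationError, FormatError, StructuralError,
                     UsageError)
from .image import ImageGrid, aspixels
from .metrics import MetricRecord, mse, ncc, psnr, ssim
from .spatial_filter import FilterKernel, apply_filter
from .vae import VAE, EncoderSpec, LossWeights, composite_loss, reparameterize
from .wavelet import dwt2, idwt2, SubbandSet

__all__ = [
    "CodecConfig",
    "TrainConfig",
    "TrainingLog",
    "CodecModel",
    "Bitstream",
    "EarlyStopper",
    "compress",
    "decompress",
    "train",
    "cross_validate",
    "rd_curve",
    "evaluate_images",
]

MAGIC = b"WCAL"
VERSION = 1
_HEADER = struct.Struct("<4sBHHBBfH8sII")  # + payload bytes
_WAVELET_IDS = {"haar": 0, "db2": 1, "db4": 2, "sym2": 3, "sym4": 4,
                "bior2.2": 5}
_WAVELET_NAMES = {v: k for k, v in _WAVELET_IDS.items()}


@dataclass(frozen=True)
class CodecConfig:
    image_hw: tuple[int, int] = (64, 64)
    wavelet: str = "haar"
    levels: int = 1
    heads: int = 8
    embed_dim: int = 64
    channels: tuple[int, ...] = (32, 64, 128, 128)
    latent_dim: int = 64
    dense_hidden: int = 128
    dropout: float = 0.3
    skip_connections: bool = False
    qstep: float = 0.1
    clip_range: int = 127

    def __post_init__(self):
        if self.wavelet not in _WAVELET_IDS:
            raise ConfigurationError(
                f"wavelet {self.wavelet!r} not in {sorted(_WAVELET_IDS)}"
            )
        if self.levels != 1:
            raise ConfigurationError(
                "the neural codec path operates on a single decomposition "
                "level (the wavelet module itself supports more)"
            )
        h, w = self.image_hw
        if h % 2 or w % 2:
            raise ConfigurationError("image dimensions must be even")

    @property
    def feature_hw(self) -> tuple[int, int]:
        return (self.image_hw[0] // 2, self.image_hw[1] // 2)

    def encoder_spec(self) -> EncoderSpec:
        n = len(self.channels)
        return EncoderSpec(
            in_channels=4, input_hw=self.feature_hw, n_conv_layers=n,
            channels=self.channels, latent_dim=self.latent_dim,
            dense_hidden=self.dense_hidden, dropout=self.dropout,
            skip_connections=self.skip_connections,
        )

    def quantizer(self, qstep: float | None = None) -> QuantizerConfig:
        return QuantizerConfig(step=qstep if qstep is not None else self.qstep,
                               clip_range=self.clip_range)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4   # 2e-4 is the documented alternative
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 32
    epochs: int = 150
    early_stopping_patience: int = 10
    seed: int = 0
    loss_mode: str = "mse"        # or "bce"
    loss_weights: LossWeights = LossWeights()

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ConfigurationError("rates and sizes must be positive")
        if self.early_stopping_patience < 1:
            raise ConfigurationError("patience must be >= 1")


@dataclass
class TrainingLog:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_recon_mse: list = field(default_factory=list)  # index 0 = pre-training
    best_epoch: int = 0
    stopped_epoch: int = 0


class EarlyStopper:
    """Stop when validation loss has not strictly improved for ``patience``
    epochs; the best epoch is the first occurrence of the best value."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = -1
        self._epoch = -1

    def update(self, loss: float) -> bool:
        """Record one epoch's validation loss; return True to stop."""
        self._epoch += 1
        if loss < self.best:
            self.best = loss
            self.best_epoch = self._epoch
        return self._epoch - self.best_epoch >= self.patience


# ---------------------------------------------------------------------------
# subband feature normalization (exact bounds for Haar on [0,1] images)
# ---------------------------------------------------------------------------


def _bands_to_features(sb: SubbandSet) -> np.ndarray:
    lv = sb.levels[0]
    ll = lv["LL"] / 2.0
    dets = [(lv[k] + 2.0) / 4.0 for k in ("LH", "HL", "HH")]
    return np.clip(np.stack([ll] + dets, axis=0), 0.0, 1.0)


def _features_to_bands(feat: np.ndarray, wavelet: str,
                       original_shape) -> SubbandSet:
    ll = feat[0] * 2.0
    lh, hl, hh = (feat[i] * 4.0 - 2.0 for i in (1, 2, 3))
    return SubbandSet([{"LL": ll, "LH": lh, "HL": hl, "HH": hh}],
                      wavelet_name=wavelet, original_shape=tuple(original_shape))


class CodecModel(nn.Module):
    """CAL block + VAE (+ optional spatial refinement filter)."""

    def __init__(self, config: CodecConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        self.cal = CALBlock(1, 3, MultiHeadConfig(config.heads, config.embed_dim),
                            rng)
        self.vae = VAE(config.encoder_spec(), rng)
        self.filter: FilterKernel | None = None
        self.trained = False

    # -- feature plumbing -----------------------------------------------------
    def features(self, images: np.ndarray) -> np.ndarray:
        """(N,H,W) images -> (N,4,h,w) normalized subband features."""
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 2:
            images = images[None]
        h, w = self.config.image_hw
        if images.shape[1:] != (h, w):
            raise StructuralError(
                f"model expects {h}x{w} images, got {images.shape[1:]}"
            )
        return np.stack([
            _bands_to_features(dwt2(im, self.config.wavelet, 1))
            for im in images
        ])

    def forward(self, feats, rng=None):
        """Normalized features -> (reconstructed features, latent posterior)."""
        feats = nn.as_tensor(feats)
        ll = feats[:, 0:1]
        hf = feats[:, 1:4]
        hf_rw = self.cal(ll, hf)
        enc_in = nn.concat([ll, hf_rw], axis=1)
        dist = self.vae.encode(enc_in)
        if self.training and rng is not None:
            z = reparameterize(dist, rng)
        else:
            z = dist.mu
        dist.z = z
        return self.vae.decode(z), dist

    # -- identity & persistence ----------------------------------------------
    @property
    def model_hash(self) -> bytes:
        h = hashlib.blake2b(digest_size=8)
        h.update(json.dumps(asdict(self.config), sort_keys=True).encode())
        for arr in self.state_arrays():
            h.update(np.ascontiguousarray(arr, dtype=np.float64).tobytes())
        return h.digest()

    def save(self, path) -> None:
        arrays = {f"array_{i:04d}": a for i, a in enumerate(self.state_arrays())}
        meta = {"format": 1, "config": asdict(self.config),
                "trained": self.trained,
                "filter": None if self.filter is None else
                          {"weights": self.filter.weights.tolist(),
                           "bias": self.filter.bias}}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "CodecModel":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["meta"]))
            arrays = [f[k] for k in sorted(k for k in f.files if k != "meta")]
        cfg = meta["config"]
        for key in ("image_hw", "channels"):
            cfg[key] = tuple(cfg[key])
        model = cls(CodecConfig(**cfg))
        model.load_state_arrays(arrays)
        model.trained = bool(meta.get("trained", True))
        filt = meta.get("filter")
        if filt is not None:
            model.filter = FilterKernel(np.array(filt["weights"]), filt["bias"])
        return model


@dataclass
class Bitstream:
    """Self-describing container for one compressed image."""

    height: int
    width: int
    wavelet_id: int
    levels: int
    qstep: float
    clip_range: int
    model_hash: bytes
    n_symbols: int
    payload: bytes
    version: int = VERSION

    @property
    def checksum(self) -> int:
        return zlib.crc32(self.payload)

    @property
    def n_bits(self) -> int:
        return 8 * (_HEADER.size + len(self.payload))

    @property
    def bpp(self) -> float:
        return self.n_bits / (self.height * self.width)

    def to_bytes(self) -> bytes:
        header = _HEADER.pack(
            MAGIC, self.version, self.height, self.width, self.wavelet_id,
            self.levels, self.qstep, self.clip_range, self.model_hash,
            self.n_symbols, self.checksum,
        )
        return header + self.payload

    @classmethod
    def from_bytes(cls, blob: bytes) -> "Bitstream":
        if len(blob) < _HEADER.size:
            raise FormatError("truncated bitstream header")
        (magic, version, h, w, wav, lev, qstep, clip, mh, n_sym,
         crc) = _HEADER.unpack_from(blob)
        if magic != MAGIC:
            raise FormatError("bad magic bytes")
        if version != VERSION:
            raise FormatError(f"unsupported container version {version}")
        payload = blob[_HEADER.size:]
        bs = cls(height=h, width=w, wavelet_id=wav, levels=lev, qstep=qstep,
                 clip_range=clip, model_hash=mh, n_symbols=n_sym,
                 payload=payload, version=version)
        if bs.checksum != crc:
            raise FormatError("payload checksum mismatch")
        return bs

    def write(self, path) -> None:
        with open(path, "wb") as fh:
            fh.write(self.to_bytes())

    @classmethod
    def read(cls, path) -> "Bitstream":
        with open(path, "rb") as fh:
            return cls.from_bytes(fh.read())


def compress(image, model: CodecModel,
             qconfig: QuantizerConfig | None = None) -> Bitstream:
    """Deterministic inference: DWT -> CAL -> posterior mean -> quantize ->
    range-code -> container."""
    if not model.trained:
        raise UsageError("model has not been trained")
    px = aspixels(image)
    qconfig = qconfig if qconfig is not None else model.config.quantizer()
    # the header carries qstep as float32; quantize with the exact value the
    # decoder will read back
    qconfig = QuantizerConfig(step=float(np.float32(qconfig.step)),
                              clip_range=qconfig.clip_range)
    model.eval()
    feats = model.features(px[None])
    _, dist = model.forward(feats)
    mu = dist.mu.data.ravel()
    stream = quantize(mu, qconfig)
    payload = encode_symbols(stream)
    return Bitstream(
        height=px.shape[0], width=px.shape[1],
        wavelet_id=_WAVELET_IDS[model.config.wavelet],
        levels=model.config.levels, qstep=qconfig.step,
        clip_range=qconfig.clip_range, model_hash=model.model_hash,
        n_symbols=len(stream), payload=payload,
    )


def decompress(bitstream: Bitstream, model: CodecModel) -> ImageGrid:
    """Invert :func:`compress`; refuses on model-hash mismatch."""
    if bitstream.model_hash != model.model_hash:
        raise UsageError(
            "bitstream was produced by a different model (hash mismatch)"
        )
    qconfig = QuantizerConfig(step=bitstream.qstep,
                              clip_range=bitstream.clip_range)
    stream = decode_symbols(bitstream.payload, qconfig.alphabet_size,
                            bitstream.n_symbols)
    z = dequantize(stream, qconfig)
    model.eval()
    feat = model.vae.decode(nn.Tensor(z[None])).data[0]
    bands = _features_to_bands(feat, model.config.wavelet,
                               (bitstream.height, bitstream.width))
    rec = idwt2(bands).pixels
    if model.filter is not None:
        rec = apply_filter(np.clip(rec, 0.0, 1.0), model.filter)
    return ImageGrid(np.clip(rec, 0.0, 1.0), peak=1.0)


def train(images: np.ndarray, split, config: TrainConfig,
          codec_config: CodecConfig | None = None,
          model: CodecModel | None = None):
    """Train the CAL + VAE stack on a dataset split.

    Returns ``(model, TrainingLog)``.  ``val_recon_mse[0]`` is the
    pre-training validation reconstruction MSE, so improvement factors can
    be read directly off the log.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim != 3:
        raise StructuralError("images must be (N, H, W)")
    if not split.train_ids or not split.val_ids:
        raise UsageError("empty training or validation split")
    if model is None:
        cc = codec_config if codec_config is not None else CodecConfig(
            image_hw=images.shape[1:]
        )
        model = CodecModel(cc, seed=config.seed)

    feats = model.features(images)
    train_x = feats[list(split.train_ids)]
    val_x = feats[list(split.val_ids)]

    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate,
                  beta1=config.beta1, beta2=config.beta2)
    stopper = EarlyStopper(config.early_stopping_patience)
    log = TrainingLog()

    def val_metrics():
        model.eval()
        recon, dist = model.forward(nn.Tensor(val_x))
        br = composite_loss(recon, nn.Tensor(val_x), dist,
                            config.loss_weights, config.loss_mode).as_floats()
        rec_mse = float(np.mean((recon.data - val_x) ** 2))
        return br.total, rec_mse

    v0, m0 = val_metrics()
    log.val_recon_mse.append(m0)
    best_state = [a.copy() for a in model.state_arrays()]
    stopper.update(v0 - 1e-12)  # epoch "-1" baseline never beats a real epoch

    n_train = train_x.shape[0]
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(n_train)
        ep_loss = 0.0
        for start in range(0, n_train, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = nn.Tensor(train_x[idx])
            opt.zero_grad()
            recon, dist = model.forward(xb, rng=rng)
            br = composite_loss(recon, xb, dist, config.loss_weights,
                                config.loss_mode)
            br.total.backward()
            opt.step()
            ep_loss += float(br.total.data) * len(idx)
        log.train_loss.append(ep_loss / n_train)

        vloss, vmse = val_metrics()
        log.val_loss.append(vloss)
        log.val_recon_mse.append(vmse)
        if vloss < stopper.best:
            best_state = [a.copy() for a in model.state_arrays()]
            log.best_epoch = epoch
        if stopper.update(vloss):
            break
    log.stopped_epoch = len(log.train_loss) - 1

    model.load_state_arrays(best_state)
    model.trained = True
    model.eval()
    return model, log


def cross_validate(images: np.ndarray, config: TrainConfig, k: int = 5,
                   codec_config: CodecConfig | None = None) -> dict:
    """k-fold driver: retrain per fold and report mean +- sd of the best
    validation reconstruction MSE across folds.

    Each fold holds out one contiguous block of the seeded shuffle as the
    validation set and trains on the rest.
    """
    images = np.asarray(images, dtype=np.float64)
    n = images.shape[0]
    if k < 2 or n < 2 * k:
        raise ConfigurationError("need k >= 2 and at least 2k images")
    perm = np.random.default_rng(config.seed).permutation(n)
    bounds = np.linspace(0, n, k + 1).astype(int)
    fold_mse = []
    for i in range(k):
        val_ids = tuple(int(x) for x in perm[bounds[i]:bounds[i + 1]])
        train_ids = tuple(int(x) for x in perm if int(x) not in set(val_ids))
        from .phantoms import DatasetSplit

        split = DatasetSplit(train_ids=train_ids, val_ids=val_ids,
                             test_ids=(), seed=config.seed)
        _, log = train(images, split, config, codec_config=codec_config)
        fold_mse.append(min(log.val_recon_mse[1:]))
    return {
        "fold_val_mse": fold_mse,
        "mean_val_mse": float(np.mean(fold_mse)),
        "sd_val_mse": float(np.std(fold_mse, ddof=1)),
    }


def rd_curve(images, model: CodecModel, qsteps) -> list[MetricRecord]:
    """Sweep quantization steps: one MetricRecord per (image, qstep)."""
    qsteps = list(qsteps)
    if len(qsteps) < 2:
        raise ConfigurationError("need at least two quantization steps")
    records = []
    for q in qsteps:
        qc = model.config.quantizer(q)
        for i, im in enumerate(images):
            records.append(
                evaluate_images(im, model, qc, image_id=f"img{i}@q={q:g}")
            )
    return records


def evaluate_images(image, model: CodecModel,
                    qconfig: QuantizerConfig | None = None,
                    image_id: str = "") -> MetricRecord:
    """Compress + decompress one image and measure the Table-style columns
    (metrics on the 0..255 scale)."""
    px = aspixels(image)
    t0 = time.perf_counter()
    bs = compress(px, model, qconfig)
    rec = decompress(bs, model).pixels
    dt = (time.perf_counter() - t0) * 1e3
    x255, y255 = px * 255.0, rec * 255.0
    return MetricRecord(
        image_id=image_id, mse=mse(x255, y255), psnr_db=psnr(x255, y255),
        ssim=ssim(x255, y255), ncc=ncc(x255, y255), bpp=bs.bpp, time_ms=dt,
    )
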