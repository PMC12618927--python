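"""Uniform scalar quantization and adaptive arithmetic (range) coding.

The latent code is quantized with a uniform mid-tread quantizer (rounding
half away from zero, symmetric clipping) and the resulting symbol stream is
compressed losslessly by an adaptive order-0 range coder: symbol counts
start at one (add-1 smoothing), are bumped after every coded symbol so the
model tracks the stream's statistics, and are halved when the total grows
past 2^16.  The coder is the carry-propagating 32-bit renormalizing variant
(cache + pending-0xFF bytes), so encode -> decode is exactly the identity
for every stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, FormatError

__all__ = [
    "QuantizerConfig",
    "SymbolStream",
    "quantize",
    "dequantize",
    "encode_symbols",
    "decode_symbols",
]

_INCREMENT = 8           # adaptation speed of the order-0 model
_MAX_TOTAL = 1 << 16     # halve counts beyond this to stay adaptive
_TOP = 1 << 24


@dataclass(frozen=True)
class QuantizerConfig:
    step: float = 0.1
    clip_range: int = 127
    subband_group_multipliers: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.step <= 0:
            raise ConfigurationError("quantizer step must be > 0")
        if self.clip_range < 1:
            raise ConfigurationError("clip_range must be >= 1")

    @property
    def alphabet_size(self) -> int:
        return 2 * self.clip_range + 1


@dataclass
class SymbolStream:
    symbols: np.ndarray
    alphabet_size: int

    def __post_init__(self):
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        if self.symbols.size and (
            self.symbols.min() < 0 or self.symbols.max() >= self.alphabet_size
        ):
            raise FormatError("symbols outside [0, alphabet_size)")

    def __len__(self):
        return self.symbols.size


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def quantize(z: np.ndarray, config: QuantizerConfig,
             step_multiplier: float = 1.0) -> SymbolStream:
    """Map latents to a non-negative alphabet: clip(round(z/step), +-R) + R."""
    z = np.asarray(z, dtype=np.float64).ravel()
    if not np.all(np.isfinite(z)):
        raise ConfigurationError("cannot quantize non-finite values")
    step = config.step * step_multiplier
    q = _round_half_away(z / step)
    q = np.clip(q, -config.clip_range, config.clip_range)
    return SymbolStream(q.astype(np.int64) + config.clip_range,
                        config.alphabet_size)


def dequantize(stream: SymbolStream, config: QuantizerConfig,
               step_multiplier: float = 1.0) -> np.ndarray:
    """Midpoint reconstruction: (symbol - R) * step."""
    if stream.alphabet_size != config.alphabet_size:
        raise FormatError("stream alphabet does not match quantizer config")
    step = config.step * step_multiplier
    return (stream.symbols - config.clip_range).astype(np.float64) * step


# ---------------------------------------------------------------------------
# range coder
# ---------------------------------------------------------------------------


class _Encoder:
    def __init__(self):
        self.low = 0
        self.range = 0xFFFFFFFF
        self.cache = 0
        self.cache_size = 1
        self.out = bytearray()

    def encode(self, cum: int, freq: int, tot: int) -> None:
        r = self.range // tot
        self.low += r * cum
        self.range = r * freq
        while self.range < _TOP:
            self.range <<= 8
            self._shift_low()

    def _shift_low(self) -> None:
        if self.low < 0xFF000000 or self.low > 0xFFFFFFFF:
            carry = self.low >> 32
            b = self.cache
            while self.cache_size:
                self.out.append((b + carry) & 0xFF)
                b = 0xFF
                self.cache_size -= 1
            self.cache = (self.low >> 24) & 0xFF
        self.cache_size += 1
        self.low = (self.low & 0x00FFFFFF) << 8

    def flush(self) -> bytes:
        for _ in range(5):
            self._shift_low()
        return bytes(self.out)


class _Decoder:
    def __init__(self, data: bytes):
        self.data = data
        self.pos = 1  # the first byte is the encoder's initial zero cache
        self.range = 0xFFFFFFFF
        self.code = 0
        for _ in range(4):
            self.code = (self.code << 8) | self._byte()
        self._r = 1

    def _byte(self) -> int:
        if self.pos < len(self.data):
            b = self.data[self.pos]
        else:
            b = 0  # tolerated: container-level checksum guards truncation
        self.pos += 1
        return b

    def decode_target(self, tot: int) -> int:
        self._r = self.range // tot
        return min(self.code // self._r, tot - 1)

    def decode_update(self, cum: int, freq: int) -> None:
        self.code -= cum * self._r
        self.range = self._r * freq
        while self.range < _TOP:
            self.code = ((self.code << 8) | self._byte()) & 0xFFFFFFFF
            self.range <<= 8


class _AdaptiveModel:
    def __init__(self, alphabet_size: int):
        self.counts = np.ones(alphabet_size, dtype=np.int64)
        self.total = alphabet_size

    def cumfreq(self, s: int) -> tuple[int, int]:
        return int(self.counts[:s].sum()), int(self.counts[s])

    def find(self, target: int) -> int:
        return int(np.searchsorted(np.cumsum(self.counts), target, side="right"))

    def update(self, s: int) -> None:
        self.counts[s] += _INCREMENT
        self.total += _INCREMENT
        if self.total >= _MAX_TOTAL:
            self.counts = (self.counts + 1) // 2
            self.total = int(self.counts.sum())


def encode_symbols(stream: SymbolStream) -> bytes:
    """Adaptive order-0 range coding; empty streams give an empty payload."""
    if len(stream) == 0:
        return b""
    enc = _Encoder()
    model = _AdaptiveModel(stream.alphabet_size)
    for s in stream.symbols:
        s = int(s)
        cum, freq = model.cumfreq(s)
        enc.encode(cum, freq, model.total)
        model.update(s)
    return enc.flush()


def decode_symbols(payload: bytes, alphabet_size: int,
                   n_symbols: int) -> SymbolStream:
    """Exact inverse of :func:`encode_symbols` with matching parameters."""
    if n_symbols == 0:
        return SymbolStream(np.empty(0, dtype=np.int64), alphabet_size)
    if not payload:
        raise FormatError("empty payload for a non-empty stream")
    dec = _Decoder(payload)
    model = _AdaptiveModel(alphabet_size)
    out = np.empty(n_symbols, dtype=np.int64)
    for i in range(n_symbols):
        target = dec.decode_target(model.total)
        s = model.find(target)
        cum, freq = model.cumfreq(s)
        dec.decode_update(cum, freq)
        model.update(s)
        out[i] = s
    return SymbolStream(out, alphabet_size)
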