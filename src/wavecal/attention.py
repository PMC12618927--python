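"""Scaled dot-product and multi-head cross-attention.

Queries are derived from low-frequency (structural) features and keys /
values from the high-frequency detail subbands, so the attention weights
express "given the local anatomy, which detail coefficients matter".  The
cross-attention (CAL) block re-weights the detail features and adds a
residual connection, emphasising or suppressing details rather than
replacing them.

All functions accept plain numpy arrays (returning arrays) or autodiff
:class:`~wavecal.nn.Tensor` inputs (returning Tensors), so the same code
path serves unit-level algebra checks and end-to-end training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, StructuralError
from .nn import Tensor, as_tensor, softmax

__all__ = [
    "MultiHeadConfig",
    "AttentionProjection",
    "scaled_dot_attention",
    "multi_head",
    "cal_block",
    "CALBlock",
]


@dataclass(frozen=True)
class MultiHeadConfig:
    h: int = 8
    embed_dim: int = 64

    def __post_init__(self):
        if self.h < 1 or self.embed_dim < 1:
            raise ConfigurationError("h and embed_dim must be >= 1")
        if self.embed_dim % self.h:
            raise ConfigurationError(
                f"embed_dim {self.embed_dim} not divisible by h {self.h}"
            )

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.h


@dataclass
class AttentionProjection:
    """Learnable projections: Q = X W_Q, K = Y W_K, V = Y W_V + b_V, output
    projected by W_o.  ``d_k`` (per-head key width) follows from the config."""

    W_Q: object
    W_K: object
    W_V: object
    W_o: object
    b_V: object | None = None

    @classmethod
    def seeded(cls, d_x: int, d_y: int, config: MultiHeadConfig,
               rng: np.random.Generator, trainable: bool = True):
        e = config.embed_dim

        def mk(fi, fo):
            return Tensor(nn.xavier_normal(rng, (fi, fo), fi, fo),
                          requires_grad=trainable)

        return cls(W_Q=mk(d_x, e), W_K=mk(d_y, e), W_V=mk(d_y, e),
                   W_o=mk(e, e), b_V=Tensor(np.zeros(e), requires_grad=trainable))


def _wants_numpy(*xs) -> bool:
    return not any(isinstance(x, Tensor) for x in xs)


def _swap_last(t: Tensor) -> Tensor:
    axes = list(range(t.ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return t.transpose(*axes)


def scaled_dot_attention(Q, K, V, return_weights: bool = False):
    """softmax(Q K^T / sqrt(d_k)) V for 2-D (tokens x dim) or batched inputs.

    Every output row is a convex combination of V's rows; the weight rows
    are non-negative and sum to 1.
    """
    to_numpy = _wants_numpy(Q, K, V)
    Q, K, V = as_tensor(Q), as_tensor(K), as_tensor(V)
    if Q.shape[-1] != K.shape[-1]:
        raise StructuralError(
            f"Q has {Q.shape[-1]} columns but K has {K.shape[-1]}"
        )
    if K.shape[-2] != V.shape[-2]:
        raise StructuralError("K and V must have equal row counts")
    d_k = Q.shape[-1]
    logits = (Q @ _swap_last(K)) * (1.0 / np.sqrt(d_k))
    weights = softmax(logits, axis=-1)
    out = weights @ V
    if to_numpy:
        out, weights = out.data, weights.data
    return (out, weights) if return_weights else out


def multi_head(X, Y, config: MultiHeadConfig, projections: AttentionProjection):
    """Eq.-style multi-head cross-attention: h independent scaled dot-product
    heads over embed_dim/h-wide slices, concatenated and projected by W_o.

    X supplies queries (tokens x d_x), Y keys and values (tokens x d_y);
    leading batch dimensions are allowed.
    """
    to_numpy = _wants_numpy(X, Y) and _wants_numpy(
        projections.W_Q, projections.W_K, projections.W_V, projections.W_o
    )
    X, Y = as_tensor(X), as_tensor(Y)
    p = projections
    Q = X @ as_tensor(p.W_Q)
    K = Y @ as_tensor(p.W_K)
    V = Y @ as_tensor(p.W_V)
    if p.b_V is not None:
        V = V + as_tensor(p.b_V)

    h, hd = config.h, config.head_dim
    batched = Q.ndim == 3

    def split(t):  # (..., T, E) -> (..., h, T, hd)
        if batched:
            n, tt = t.shape[0], t.shape[1]
            return t.reshape(n, tt, h, hd).transpose(0, 2, 1, 3)
        tt = t.shape[0]
        return t.reshape(tt, h, hd).transpose(1, 0, 2)

    heads = scaled_dot_attention(split(Q), split(K), split(V))
    if batched:
        n, tt = Q.shape[0], Q.shape[1]
        concatd = heads.transpose(0, 2, 1, 3).reshape(n, tt, h * hd)
    else:
        tt = Q.shape[0]
        concatd = heads.transpose(1, 0, 2).reshape(tt, h * hd)
    out = concatd @ as_tensor(p.W_o)
    return out.data if to_numpy else out


class CALBlock(nn.Module):
    """Cross-attention reweighting of high-frequency subband features.

    Feature maps are tokenized per spatial position (H*W tokens, channels as
    features), linearly embedded to ``embed_dim``; queries come from the LL
    map, keys/values from the detail maps.  The attended features are
    projected back to the detail channel count and added to the input
    (residual), so at zero-initialized value/output paths the block is the
    identity on the details.
    """

    def __init__(self, ll_channels: int, hf_channels: int,
                 config: MultiHeadConfig = MultiHeadConfig(),
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.config = config
        self.embed_q = nn.Linear(ll_channels, config.embed_dim, rng, bias=False)
        self.embed_kv = nn.Linear(hf_channels, config.embed_dim, rng, bias=False)
        self.proj = AttentionProjection.seeded(
            config.embed_dim, config.embed_dim, config, rng
        )
        # the projection dataclass is not a Module; register its tensors
        self.proj_params = [self.proj.W_Q, self.proj.W_K, self.proj.W_V,
                            self.proj.W_o, self.proj.b_V]
        self.unembed = nn.Linear(config.embed_dim, hf_channels, rng)

    def forward(self, ll, hf):
        ll, hf = as_tensor(ll), as_tensor(hf)
        if ll.ndim != 4 or hf.ndim != 4 or ll.shape[2:] != hf.shape[2:]:
            raise StructuralError(
                "expected NCHW maps with matching spatial shapes"
            )
        n, c_hf, hgt, wid = hf.shape
        t = hgt * wid

        def tokens(x):  # (N,C,H,W) -> (N, T, C)
            return x.reshape(x.shape[0], x.shape[1], t).transpose(0, 2, 1)

        q_tok = self.embed_q(tokens(ll))
        kv_tok = self.embed_kv(tokens(hf))
        attended = multi_head(q_tok, kv_tok, self.config, self.proj)
        delta = self.unembed(attended)  # (N, T, C_hf)
        delta_map = delta.transpose(0, 2, 1).reshape(n, c_hf, hgt, wid)
        return hf + delta_map


def cal_block(ll_features, hf_features,
              config: MultiHeadConfig = MultiHeadConfig(),
              block: CALBlock | None = None, seed: int = 0):
    """Functional wrapper around :class:`CALBlock`.

    Accepts (C,H,W) or (N,C,H,W) feature maps; when no block is supplied a
    fresh one is built deterministically from ``seed``.
    """
    to_numpy = _wants_numpy(ll_features, hf_features)
    ll, hf = as_tensor(ll_features), as_tensor(hf_features)
    squeeze = ll.ndim == 3
    if squeeze:
        ll = ll.reshape(1, *ll.shape)
        hf = hf.reshape(1, *hf.shape)
    if block is None:
        block = CALBlock(ll.shape[1], hf.shape[1], config,
                         np.random.default_rng(seed))
    out = block(ll, hf)
    if squeeze:
        out = out.reshape(*out.shape[1:])
    return out.data if to_numpy else out
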