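"""Decoder attention: tokenization, positional encoding, MHSA and FFN.

After every decoder upsampling the concatenated (upsampled + skip) feature
map passes through one transformer encoder layer.  The map is first cut into
non-overlapping ``patch x patch`` tiles, each flattened to a token (patch 1
means one token per pixel); tokens are linearly embedded to a fixed model
width, given sinusoidal positional offsets, run through multi-head
self-attention and a position-wise feed-forward network - each sub-layer
wrapped in a residual Add & Norm - then projected back to the original
channel layout.  The whole block is shape preserving.

Per head i the attention output is ``softmax(Q_i K_i^T / sqrt(d_h)) V_i``
with Q, K, V obtained by learned linear maps of the tokens; head outputs are
concatenated and mixed by a final projection.  The feed-forward network is
``max(0, X W1 + b1) W2 + b2``.
"""

from __future__ import annotations

import math

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "tokenize", "detokenize", "positional_encoding",
    "MultiHeadSelfAttention", "FeedForward", "TokenEncoderLayer",
    "TransformerBlock2d", "mhsa", "ffn",
]


# -- tokenization -----------------------------------------------------------

def tokenize(x: Tensor | np.ndarray, patch: int) -> Tensor:
    """Cut an NHWC map into non-overlapping patches, one token per patch.

    Lossless and exactly invertible via :func:`detokenize`; with ``patch=1``
    the token dim equals the channel count.
    """
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
    n, h, w, c = t.shape
    if h % patch or w % patch:
        raise ValueError(
            f"spatial dims {h}x{w} not divisible by patch size {patch}")
    t = t.reshape(n, h // patch, patch, w // patch, patch, c)
    t = t.transpose(0, 1, 3, 2, 4, 5)
    return t.reshape(n, (h // patch) * (w // patch), patch * patch * c)


def detokenize(tokens: Tensor | np.ndarray, height: int, width: int,
               patch: int) -> Tensor:
    """Inverse of :func:`tokenize` for the given spatial origin."""
    t = tokens if isinstance(tokens, Tensor) else Tensor(np.asarray(tokens))
    n, length, dim = t.shape
    hp, wp = height // patch, width // patch
    if length != hp * wp or dim % (patch * patch):
        raise ValueError("token sequence does not match the stated origin")
    c = dim // (patch * patch)
    t = t.reshape(n, hp, wp, patch, patch, c)
    t = t.transpose(0, 1, 3, 2, 4, 5)
    return t.reshape(n, height, width, c)


def positional_encoding(length: int, dim: int) -> np.ndarray:
    """Fixed sinusoidal table, shape (length, dim), values in [-1, 1].

    Even columns carry sin(pos / 10000^(2i/dim)), odd columns the matching
    cos; rows are pairwise distinct for any practical sequence length.
    """
    if dim % 2:
        raise ValueError(f"positional encoding needs an even dim, got {dim}")
    pos = np.arange(length, dtype=np.float64)[:, None]
    i = np.arange(dim // 2, dtype=np.float64)[None, :]
    angle = pos / np.power(10000.0, 2.0 * i / dim)
    table = np.zeros((length, dim), dtype=np.float64)
    table[:, 0::2] = np.sin(angle)
    table[:, 1::2] = np.cos(angle)
    return table


# -- layers -----------------------------------------------------------------

class MultiHeadSelfAttention(nn.Module):
    """Scaled dot-product attention over ``heads`` parallel heads.

    ``heads * head_dim == dim``; attention rows are probability vectors.
    The scale 1/sqrt(head_dim) stabilises the softmax logits.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if heads < 1 or dim % heads:
            raise ValueError(f"head count {heads} must divide dim {dim}")
        self.dim = dim
        self.heads = heads
        self.head_dim = dim // heads
        self.wq = nn.Linear(dim, dim, rng=rng)
        self.wk = nn.Linear(dim, dim, rng=rng)
        self.wv = nn.Linear(dim, dim, rng=rng)
        self.wo = nn.Linear(dim, dim, rng=rng)
        self.last_attention: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 3 or x.shape[-1] != self.dim:
            raise ValueError(
                f"expected (batch, tokens, {self.dim}) sequence, got {x.shape}")
        n, t, _ = x.shape
        h, dh = self.heads, self.head_dim

        def split(z: Tensor) -> Tensor:
            return z.reshape(n, t, h, dh).transpose(0, 2, 1, 3)

        q = split(self.wq(x))
        k = split(self.wk(x))
        v = split(self.wv(x))
        scores = nn.matmul(q, k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        attn = nn.softmax(scores, axis=-1)
        self.last_attention = attn.data
        mixed = nn.matmul(attn, v)
        merged = mixed.transpose(0, 2, 1, 3).reshape(n, t, self.dim)
        return self.wo(merged)


class FeedForward(nn.Module):
    """Position-wise FFN(X) = max(0, X W1 + b1) W2 + b2."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.lin1 = nn.Linear(dim, hidden, rng=rng)
        self.lin2 = nn.Linear(hidden, dim, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.lin2(nn.relu(self.lin1(x)))


class TokenEncoderLayer(nn.Module):
    """MHSA and FFN sub-layers, each wrapped in residual Add & Norm.

    ``norm_placement``: "post" (Add then Norm, the default) or "pre"
    (normalise the sub-layer input, residual outside).
    """

    def __init__(self, dim: int, heads: int, ffn_dim: int,
                 rng: np.random.Generator, norm_placement: str = "post"):
        super().__init__()
        if norm_placement not in ("post", "pre"):
            raise ValueError(f"unknown norm placement {norm_placement!r}")
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.norm1 = nn.LayerNorm(dim)
        self.ffn = FeedForward(dim, ffn_dim, rng)
        self.norm2 = nn.LayerNorm(dim)
        self.norm_placement = norm_placement

    def forward(self, x: Tensor) -> Tensor:
        if self.norm_placement == "post":
            x = self.norm1(x + self.attn(x))
            x = self.norm2(x + self.ffn(x))
        else:
            x = x + self.attn(self.norm1(x))
            x = x + self.ffn(self.norm2(x))
        return x


class TransformerBlock2d(nn.Module):
    """Shape-preserving transformer block applied to a decoder feature map.

    tokenize -> linear embed (fixed ``embed_dim``) -> + positional encoding
    -> MHSA -> Add & Norm -> FFN -> Add & Norm -> linear un-embed
    -> detokenize.  The fixed embedding width keeps the attention parameter
    count independent of the stage's channel * patch^2 product, which is what
    makes a single calibrated width schedule reproduce the reference
    parameter budget.
    """

    def __init__(self, channels: int, patch: int, embed_dim: int, heads: int,
                 ffn_dim: int, rng: np.random.Generator,
                 norm_placement: str = "post",
                 use_positional_encoding: bool = True):
        super().__init__()
        if patch < 1:
            raise ValueError("patch size must be >= 1")
        self.channels = channels
        self.patch = patch
        token_dim = channels * patch * patch
        self.embed = nn.Linear(token_dim, embed_dim, rng=rng)
        self.encoder = TokenEncoderLayer(embed_dim, heads, ffn_dim, rng,
                                         norm_placement)
        self.unembed = nn.Linear(embed_dim, token_dim, rng=rng)
        self.embed_dim = embed_dim
        self.use_positional_encoding = use_positional_encoding
        self._pe_cache: dict[int, np.ndarray] = {}

    def forward(self, x: Tensor) -> Tensor:
        n, h, w, c = x.shape
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        tokens = tokenize(x, self.patch)
        z = self.embed(tokens)
        if self.use_positional_encoding:
            length = z.shape[1]
            pe = self._pe_cache.get(length)
            if pe is None:
                pe = positional_encoding(length, self.embed_dim).astype(
                    np.float32)
                self._pe_cache[length] = pe
            z = z + Tensor(pe)
        z = self.encoder(z)
        out = self.unembed(z)
        return detokenize(out, h, w, self.patch)


# -- functional forms used by the brute-force oracles -----------------------

def mhsa(x: np.ndarray, layer: MultiHeadSelfAttention) -> np.ndarray:
    """Run a token sequence (tokens, dim) or batch through an MHSA layer."""
    arr = np.asarray(x, dtype=np.float32)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[None]
    with nn.no_grad():
        out = layer(Tensor(arr))
    return out.data[0] if squeeze else out.data


def ffn(x: np.ndarray, w1: np.ndarray, b1: np.ndarray, w2: np.ndarray,
        b2: np.ndarray) -> np.ndarray:
    """Position-wise feed-forward on a plain array (no parameters learned)."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != np.asarray(w1).shape[0]:
        raise ValueError("token dim does not match W1")
    return np.maximum(x @ w1 + b1, 0.0) @ w2 + b2
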