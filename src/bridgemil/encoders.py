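"""Unimodal encoders.

The slide encoder is a transformer multiple-instance-learning network: a
linear projection of patch embeddings, sequence squaring, a class token,
two self-attention layers with a pyramid convolutional positional encoding
between them, and the class token as the slide embedding. Patch-level
attention is the class-token row of the final attention layer, averaged
over heads and min-max normalized.

The omics encoder is a self-normalizing MLP (SELU activations, lecun
initialization, alpha-dropout), the standard choice for wide, sample-poor
omics tables where plain ReLU nets overfit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import EncoderConfig
from .io import PatchBag
from .nn import (Tensor, concat, softmax, exact_attention, nystrom_attention,
                 LayerNorm, Linear, Module, SNNBlock)

__all__ = ["SlideEmbedding", "OmicsEmbedding", "TransMILEncoder",
           "GatedAttentionEncoder", "SNNEncoder", "build_wsi_encoder"]


@dataclass
class SlideEmbedding:
    patient_id: str
    vector: np.ndarray       # (d_wsi,)
    attention: np.ndarray    # (N_patches,), min-max normalized to [0, 1]


@dataclass
class OmicsEmbedding:
    patient_id: str
    vector: np.ndarray       # (d_omics,)


def minmax_normalize(scores: np.ndarray) -> np.ndarray:
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        return np.zeros_like(scores)
    return (scores - lo) / (hi - lo)


class MultiHeadSelfAttention(Module):
    """Self-attention over a token sequence, exact or Nystrom-approximated.

    The exact path is used whenever the sequence is short enough
    (tokens <= exact_attention_ratio * n_landmarks); the Nystrom path
    exists for long patch sequences.
    """

    def __init__(self, d: int, n_heads: int, n_landmarks: int,
                 exact_ratio: int, rng: np.random.Generator):
        super().__init__()
        if d % n_heads:
            raise ValueError("d must be divisible by n_heads")
        self.d, self.h = d, n_heads
        self.n_landmarks = n_landmarks
        self.exact_ratio = exact_ratio
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)
        self.last_cls_attention: np.ndarray | None = None  # detached cache

    def __call__(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        dh = self.d // self.h

        def split(t: Tensor) -> Tensor:           # (n, d) -> (h, n, dh)
            return t.reshape(n, self.h, dh).transpose(1, 0, 2)

        Q, K, V = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        if n <= self.exact_ratio * self.n_landmarks:
            out, cls_row = exact_attention(Q, K, V)
        else:
            out, cls_row = nystrom_attention(Q, K, V, self.n_landmarks)
        self.last_cls_attention = cls_row.data.mean(axis=0)  # head average
        out = out.transpose(1, 0, 2).reshape(n, self.d)
        return self.wo(out)


class TransLayer(Module):
    """Pre-norm residual attention block."""

    def __init__(self, d: int, n_heads: int, n_landmarks: int,
                 exact_ratio: int, rng: np.random.Generator):
        super().__init__()
        self.norm = LayerNorm(d)
        self.attn = MultiHeadSelfAttention(d, n_heads, n_landmarks,
                                           exact_ratio, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return x + self.attn(self.norm(x))


class PPEG(Module):
    """Pyramid positional encoding: depthwise convolutions (kernels 7/5/3
    by default) over the square token grid, summed residually; the class
    token bypasses the convolution."""

    def __init__(self, d: int, kernels: tuple[int, ...],
                 rng: np.random.Generator):
        super().__init__()
        self.kernels = [
            Tensor(rng.normal(0.0, 1.0 / (k * k), size=(k, k, d)),
                   requires_grad=True)
            for k in kernels
        ]

    def __call__(self, x: Tensor) -> Tensor:
        m = x.shape[0] - 1
        side = int(round(np.sqrt(m)))
        cls, feat = x[0:1, :], x[1:, :]
        grid = feat.reshape(side, side, -1)
        out = grid
        for k in self.kernels:
            out = out + grid.depthwise_conv2d(k)
        return concat([cls, out.reshape(m, -1)], axis=0)


class TransMILEncoder(Module):
    """PatchBag -> slide embedding + per-patch attention scores."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        d = cfg.d_wsi
        self.proj = Linear(cfg.patch_dim, d, rng)
        self.cls_token = Tensor(rng.normal(0.0, 0.02, size=(1, d)),
                                requires_grad=True)
        self.layers = [TransLayer(d, cfg.n_heads, cfg.n_landmarks,
                                  cfg.exact_attention_ratio, rng)
                       for _ in range(cfg.n_layers)]
        self.ppeg = PPEG(d, cfg.ppeg_kernels, rng) if cfg.use_ppeg else None
        self.norm = LayerNorm(d)

    def forward(self, features: np.ndarray) -> tuple[Tensor, np.ndarray]:
        """Returns (embedding Tensor (d,), raw class-attention over the
        original N patches as a numpy array)."""
        n = features.shape[0]
        if n < 1:
            raise ValueError("bag must contain at least one patch")
        x = self.proj(Tensor(features)).relu()
        # square the sequence: pad to M = ceil(sqrt(N))^2 by repeating the
        # first M - N tokens
        m = int(np.ceil(np.sqrt(n))) ** 2
        if m > n:
            x = concat([x, x[0:m - n, :]], axis=0)
        x = concat([self.cls_token, x], axis=0)
        x = self.layers[0](x)
        if self.ppeg is not None:
            x = self.ppeg(x)
        for layer in self.layers[1:]:
            x = layer(x)
        x = self.norm(x)
        emb = x[0, :]
        raw = self.layers[-1].attn.last_cls_attention[1:n + 1].copy()
        return emb, raw

    def encode_slide(self, bag: PatchBag) -> SlideEmbedding:
        bag.validate()
        emb, raw = self.forward(bag.features)
        return SlideEmbedding(bag.patient_id, emb.data.copy(),
                              minmax_normalize(raw))


class GatedAttentionEncoder(Module):
    """Gated attention-pooling MIL baseline (AMIL-style): permutation
    invariant, no positional encoding."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator,
                 d_gate: int = 64):
        super().__init__()
        self.cfg = cfg
        d = cfg.d_wsi
        self.proj = Linear(cfg.patch_dim, d, rng)
        self.gate_v = Linear(d, d_gate, rng)
        self.gate_u = Linear(d, d_gate, rng)
        self.gate_w = Linear(d_gate, 1, rng, bias=False)

    def forward(self, features: np.ndarray) -> tuple[Tensor, np.ndarray]:
        if features.shape[0] < 1:
            raise ValueError("bag must contain at least one patch")
        h = self.proj(Tensor(features)).relu()
        scores = self.gate_w(self.gate_v(h).tanh() * self.gate_u(h).sigmoid())
        a = softmax(scores.reshape(1, -1), axis=-1)
        emb = (a @ h)[0, :]
        return emb, a.data[0].copy()

    def encode_slide(self, bag: PatchBag) -> SlideEmbedding:
        bag.validate()
        emb, raw = self.forward(bag.features)
        return SlideEmbedding(bag.patient_id, emb.data.copy(),
                              minmax_normalize(raw))


def build_wsi_encoder(cfg: EncoderConfig, rng: np.random.Generator) -> Module:
    if cfg.wsi_pooling == "transformer":
        return TransMILEncoder(cfg, rng)
    if cfg.wsi_pooling == "gated_attention":
        return GatedAttentionEncoder(cfg, rng)
    raise ValueError(f"unknown wsi_pooling {cfg.wsi_pooling!r}")


class SNNEncoder(Module):
    """Self-normalizing MLP: standardized omics vector -> embedding."""

    def __init__(self, n_features: int, cfg: EncoderConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.n_features = n_features
        self.block1 = SNNBlock(n_features, cfg.snn_hidden, rng,
                               cfg.snn_dropout)
        self.block2 = SNNBlock(cfg.snn_hidden, cfg.d_omics, rng,
                               cfg.snn_dropout)

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.shape[-1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {x.shape[-1]}")
        return self.block2(self.block1(x))

    def encode_omics(self, patient_id: str, values: np.ndarray
                     ) -> OmicsEmbedding:
        was_training = self.training
        self.eval()
        out = self.forward(values.reshape(1, -1))
        self.train(was_training)
        return OmicsEmbedding(patient_id, out.data[0].copy())
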