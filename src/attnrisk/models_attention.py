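"""Temporal attention architectures for visit sequences.

Two architectures are provided:

* :class:`RetainNet` — the two-level attention recurrent network: visit
  embeddings are read by two bidirectional LSTMs, one producing a scalar
  (softmax) attention per visit, the other a per-coordinate tanh gate; the
  context vector is the attention-weighted sum of gated visit embeddings
  and feeds a logistic output layer.  Age, sex and the (scaled) visit time
  are concatenated to each visit embedding.
* :class:`TransformerNet` — sum-of-concept-embedding visit vectors with
  age/sex concatenated, projected to the model width, plus a sinusoidal
  embedding of the day offset before index; a stack of pre-norm multi-head
  self-attention blocks; and a 1-D convolutional prediction head (two
  kernel-3 convolutions, masked max-pool, linear).  A diagnostic
  mean-pool head replaces the convolutions for permutation checks.

Sequences are padded per batch and masked everywhere: padded visits carry
exactly zero attention and do not contribute to pooling.  Observations
with no qualifying events are represented by a single learned null-visit
token so their static covariates still reach the predictor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concatenate, softmax, tanh
from .nn import (LSTM, Conv1dSame, Embedding, LayerNorm, Linear, Module,
                 MultiHeadSelfAttention, dropout)

__all__ = [
    "RetainConfig", "TransformerConfig", "AttentionOutput", "SequenceBatch",
    "RetainNet", "TransformerNet", "pack_sequences",
    "sinusoidal_time_embedding", "embed_visits",
    "retain_forward", "transformer_forward",
]


# -- batching --------------------------------------------------------------

@dataclass
class SequenceBatch:
    """Padded + masked batch of visit sequences.

    ``concept_idx`` (B,T,C) indexes the embedding table (row ``null_index``
    is the learned null-visit token); ``concept_mask`` marks real concepts,
    ``visit_mask`` real visits; ``days`` holds days-before-index.
    """

    concept_idx: np.ndarray
    concept_mask: np.ndarray
    visit_mask: np.ndarray
    days: np.ndarray
    static: np.ndarray
    obs_ids: np.ndarray

    def __len__(self):
        return self.concept_idx.shape[0]

    def take(self, idx) -> "SequenceBatch":
        return SequenceBatch(self.concept_idx[idx], self.concept_mask[idx],
                             self.visit_mask[idx], self.days[idx],
                             self.static[idx], self.obs_ids[idx])


def pack_sequences(sequences, n_concepts: int, max_visits: int = 50) -> SequenceBatch:
    """Pad a list of :class:`~attnrisk.features.VisitSequence` into arrays.

    Empty sequences become a single null-token visit at day offset 0.
    """
    null_index = n_concepts
    B = len(sequences)
    T = max(1, min(max_visits, max((len(s.visits) for s in sequences), default=1)))
    C = 1
    for s in sequences:
        for _, cs in s.visits:
            C = max(C, len(cs))
    cidx = np.full((B, T, C), null_index, dtype=np.int64)
    cmask = np.zeros((B, T, C), dtype=bool)
    vmask = np.zeros((B, T), dtype=bool)
    days = np.zeros((B, T), dtype=float)
    static = np.zeros((B, len(sequences[0].static)), dtype=float)
    obs = np.zeros(B, dtype=np.int64)
    for b, s in enumerate(sequences):
        visits = s.visits[-max_visits:] if len(s.visits) > max_visits else s.visits
        if not visits:
            visits = [(0, (null_index,))]
        for t, (d, cs) in enumerate(visits):
            cidx[b, t, :len(cs)] = cs
            cmask[b, t, :len(cs)] = True
            days[b, t] = d
            vmask[b, t] = True
        static[b] = s.static
        obs[b] = s.observation_id
    return SequenceBatch(cidx, cmask, vmask, days, static, obs)


# -- shared pieces ---------------------------------------------------------

def sinusoidal_time_embedding(days: np.ndarray, dim: int, base: float = 10000.0) -> np.ndarray:
    """Standard interleaved sin/cos positional encoding at day offsets.

    ``out[..., 2i] = sin(d * base**(-2i/dim))``,
    ``out[..., 2i+1] = cos(d * base**(-2i/dim))``; values lie in [-1, 1].
    """
    if dim % 2:
        raise ValueError("time embedding dimension must be even")
    days = np.asarray(days, dtype=float)
    freqs = base ** (-np.arange(0, dim, 2) / dim)
    ang = days[..., None] * freqs
    out = np.empty(days.shape + (dim,))
    out[..., 0::2] = np.sin(ang)
    out[..., 1::2] = np.cos(ang)
    return out


def embed_visits(batch: SequenceBatch, table: Tensor,
                 include_static: bool = True, include_time: bool = False,
                 obs_window_days: int = 365) -> Tensor:
    """Sum concept embeddings per visit and concatenate static covariates.

    The visit embedding is the masked sum of its concepts' embedding rows;
    age and sex (and, when ``include_time``, days_before_index scaled by
    the observation window) are appended per visit.
    """
    if batch.concept_idx.max() >= table.shape[0]:
        raise IndexError("concept index outside the embedding table")
    emb = table[batch.concept_idx]                      # (B,T,C,E)
    emb = emb * Tensor(batch.concept_mask[..., None].astype(float))
    visit = emb.sum(axis=2)                             # (B,T,E)
    if not (include_static or include_time):
        return visit
    B, T = batch.visit_mask.shape
    extras = [visit]
    if include_static:
        extras.append(Tensor(np.repeat(batch.static[:, None, :], T, axis=1)))
    if include_time:
        extras.append(Tensor((batch.days / obs_window_days)[..., None]))
    return concatenate(extras, axis=-1)


def _masked_softmax_over_visits(scores: Tensor, visit_mask: np.ndarray) -> Tensor:
    """Softmax over the visit axis; padded visits get exactly zero weight."""
    masked = scores + Tensor(np.where(visit_mask, 0.0, -1e9))
    att = softmax(masked, axis=1)
    return att * Tensor(visit_mask.astype(float))


@dataclass
class AttentionOutput:
    scores: np.ndarray                 # risk in (0,1) per observation
    visit_attention: np.ndarray        # (B, T), zeros on padding
    coordinate_attention: np.ndarray | None = None  # (B, T, E), RETAIN only


# -- configurations --------------------------------------------------------

@dataclass
class RetainConfig:
    embedding_dim: int = 16
    lstm_hidden_dim: int = 16
    dropout: float = 0.0
    include_static: bool = True

    def __post_init__(self):
        if min(self.embedding_dim, self.lstm_hidden_dim) <= 0:
            raise ValueError("dimensions must be positive")


@dataclass
class TransformerConfig:
    embedding_dim: int = 16
    num_heads: int = 2
    attn_depth: int = 1
    num_hidden: int = 32
    dropout: float = 0.0
    conv_width: int = 16
    head: str = "conv"        # "conv" | "mean" (diagnostic)

    def __post_init__(self):
        if self.embedding_dim % self.num_heads:
            raise ValueError("embedding_dim must be divisible by num_heads")


# -- RETAIN ----------------------------------------------------------------

class RetainNet(Module):
    def __init__(self, n_concepts: int, config: RetainConfig,
                 n_static: int = 2, seed: int = 0, obs_window_days: int = 365):
        super().__init__()
        self.config = config
        self.obs_window_days = obs_window_days
        rng = np.random.default_rng(seed)
        E = config.embedding_dim
        self.embedding = Embedding(n_concepts + 1, E, rng)  # +1: null visit token
        vis_dim = E + (n_static + 1 if config.include_static else 0)  # +1: visit time
        self.vis_dim = vis_dim
        H = config.lstm_hidden_dim
        self.lstm_alpha = LSTM(vis_dim, H, rng, bidirectional=True)
        self.lstm_beta = LSTM(vis_dim, H, rng, bidirectional=True)
        self.alpha_proj = Linear(2 * H, 1, rng)
        self.beta_proj = Linear(2 * H, vis_dim, rng)
        self.out = Linear(vis_dim, 1, rng)
        self._rng = rng

    def forward(self, batch: SequenceBatch, return_attention: bool = False):
        cfg = self.config
        e = embed_visits(batch, self.embedding.table,
                         include_static=cfg.include_static,
                         include_time=cfg.include_static,
                         obs_window_days=self.obs_window_days)
        e = dropout(e, cfg.dropout, self._rng, self.training)
        h_a = self.lstm_alpha(e, batch.visit_mask)
        h_b = self.lstm_beta(e, batch.visit_mask)
        alpha = _masked_softmax_over_visits(self.alpha_proj(h_a), batch.visit_mask[..., None])
        beta = tanh(self.beta_proj(h_b))
        context = (alpha * beta * e).sum(axis=1)        # (B, vis_dim)
        logits = self.out(context).reshape(-1)
        if return_attention:
            return logits, alpha.data[..., 0], beta.data
        return logits

    __call__ = forward


# -- transformer -----------------------------------------------------------

class _TransformerBlock(Module):
    """Pre-norm: x + MHSA(LN(x)); x + FFN(LN(x))."""

    def __init__(self, dim: int, num_heads: int, num_hidden: int,
                 rng: np.random.Generator):
        super().__init__()
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, num_heads, rng)
        self.ln2 = LayerNorm(dim)
        self.ff1 = Linear(dim, num_hidden, rng)
        self.ff2 = Linear(num_hidden, dim, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        x = x + self.attn(self.ln1(x), mask)
        return x + self.ff2(self.ff1(self.ln2(x)).relu())


class TransformerNet(Module):
    def __init__(self, n_concepts: int, config: TransformerConfig,
                 n_static: int = 2, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        E = config.embedding_dim
        self.embedding = Embedding(n_concepts + 1, E, rng)
        self.in_proj = Linear(E + n_static, E, rng)
        self.blocks = [_TransformerBlock(E, config.num_heads, config.num_hidden, rng)
                       for _ in range(config.attn_depth)]
        self.ln_final = LayerNorm(E)
        W = config.conv_width
        self.conv1 = Conv1dSame(E, W, rng, kernel=3)
        self.conv2 = Conv1dSame(W, W, rng, kernel=3)
        self.head_conv = Linear(W, 1, rng)
        self.head_mean = Linear(E, 1, rng)
        self._rng = rng

    def forward(self, batch: SequenceBatch, return_attention: bool = False):
        cfg = self.config
        x = embed_visits(batch, self.embedding.table, include_time=False)
        x = self.in_proj(x)
        x = x + Tensor(sinusoidal_time_embedding(batch.days, cfg.embedding_dim))
        x = dropout(x, cfg.dropout, self._rng, self.training)
        for blk in self.blocks:
            x = blk(x, batch.visit_mask)
        x = self.ln_final(x)
        vmask = Tensor(batch.visit_mask[..., None].astype(float))
        x = x * vmask  # padded positions contribute nothing downstream
        if cfg.head == "mean":
            denom = batch.visit_mask.sum(axis=1, keepdims=True).astype(float)
            pooled = x.sum(axis=1) * Tensor(1.0 / denom)
            logits = self.head_mean(pooled).reshape(-1)
        else:
            h = self.conv1(x).relu() * vmask
            h = self.conv2(h).relu()
            # masked max-pool over time
            h = h + Tensor(np.where(batch.visit_mask[..., None], 0.0, -1e9))
            pooled = h.max(axis=1)
            logits = self.head_conv(pooled).reshape(-1)
        if return_attention:
            att = self.blocks[-1].attn.last_weights  # (B, heads, T, T)
            # average over heads and queries (real visits only) -> per-key weight
            qmask = batch.visit_mask[:, None, :, None].astype(float)
            per_key = (att * qmask).sum(axis=(1, 2))
            denom = per_key.sum(axis=-1, keepdims=True)
            per_key = np.divide(per_key, denom, out=np.zeros_like(per_key),
                                where=denom > 0)
            return logits, per_key
        return logits

    __call__ = forward


# -- functional wrappers ---------------------------------------------------

def retain_forward(batch: SequenceBatch, model: RetainNet) -> AttentionOutput:
    model.eval()
    logits, alpha, beta = model.forward(batch, return_attention=True)
    return AttentionOutput(scores=1.0 / (1.0 + np.exp(-logits.data)),
                           visit_attention=alpha, coordinate_attention=beta)


def transformer_forward(batch: SequenceBatch, model: TransformerNet) -> AttentionOutput:
    model.eval()
    logits, att = model.forward(batch, return_attention=True)
    return AttentionOutput(scores=1.0 / (1.0 + np.exp(-logits.data)),
                           visit_attention=att)
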