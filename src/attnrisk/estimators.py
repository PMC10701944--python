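"""Scikit-learn-style estimators over the temporal attention networks.

``X`` for these estimators is a list of
:class:`~attnrisk.features.VisitSequence` (the temporal view produced by
:func:`attnrisk.features.build_sequences`); ``y`` is the binary outcome.
Each estimator packs the sequences into padded/masked arrays, trains with
class-weighted BCE (Adam, early stopping on a validation fold, LR decay)
and exposes ``predict_proba``.  :class:`SardClassifier` adds reverse
distillation: the transformer is first trained to match a linear teacher's
logits, then finetuned on an alpha-blend of teacher matching and label
loss.
"""

from __future__ import annotations

import contextlib

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import autodiff
from .features import VisitSequence
from .models_attention import (RetainConfig, RetainNet, SequenceBatch,
                               TransformerConfig, TransformerNet, pack_sequences)
from .training import (TrainConfig, TrainingHistory, distill, finetune,
                       train)

__all__ = ["RetainClassifier", "TransformerClassifier", "SardClassifier"]


@contextlib.contextmanager
def _train_dtype(dtype):
    """Build and train under ``dtype`` (float32 by default: ~2x faster on
    these model sizes), restoring the engine default afterwards."""
    old = autodiff.DTYPE
    autodiff.set_dtype(dtype)
    try:
        yield
    finally:
        autodiff.set_dtype(old)


def _infer_n_concepts(sequences) -> int:
    m = -1
    for s in sequences:
        for _, cs in s.visits:
            if cs:
                m = max(m, max(cs))
    return m + 1


class _SequenceClassifier(ClassifierMixin, BaseEstimator):
    def __init__(self, *, n_concepts=None, max_visits=50, lr=1e-2,
                 batch_size=512, max_epochs=30, early_stop_patience=3,
                 dtype="float32", random_state=0):
        self.n_concepts = n_concepts
        self.max_visits = max_visits
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.dtype = dtype
        self.random_state = random_state

    # subclasses build the network
    def _build_net(self, n_concepts: int):
        raise NotImplementedError

    def _train_config(self, **over) -> TrainConfig:
        base = dict(batch_size=self.batch_size, max_epochs=self.max_epochs,
                    early_stop_patience=self.early_stop_patience, lr=self.lr,
                    seed=self.random_state)
        base.update(over)
        return TrainConfig(**base)

    def _pack(self, X) -> SequenceBatch:
        if isinstance(X, SequenceBatch):
            return X
        if not all(isinstance(s, VisitSequence) for s in X):
            raise TypeError("X must be a list of VisitSequence")
        return pack_sequences(X, self.n_concepts_, max_visits=self.max_visits)

    def fit(self, X, y, X_val=None, y_val=None, epoch_schedule=None):
        y = np.asarray(y).astype(int)
        self.n_concepts_ = (self.n_concepts if self.n_concepts is not None
                            else _infer_n_concepts(X))
        self.classes_ = np.array([0, 1])
        with _train_dtype(self.dtype):
            self.net_ = self._build_net(self.n_concepts_)
            batch = self._pack(X)
            val_batch = self._pack(X_val) if X_val is not None else None
            self.history_ = train(
                self.net_, batch, y, self._train_config(),
                val_batch=val_batch,
                val_labels=None if y_val is None else np.asarray(y_val),
                epoch_schedule=epoch_schedule)
        return self

    def refit(self, X, y):
        """Refit on the full development fold, replaying the LR schedule
        recorded up to the best epoch of the monitored fit."""
        if not hasattr(self, "history_") or self.history_.best_epoch < 1:
            raise RuntimeError("refit requires a previous monitored fit")
        schedule = self.history_.lr[:self.history_.best_epoch]
        return self.fit(X, y, epoch_schedule=schedule)

    def decision_function(self, X) -> np.ndarray:
        batch = self._pack(X)
        self.net_.eval()
        out = np.empty(len(batch))
        for start in range(0, len(batch), 1024):
            idx = np.arange(start, min(start + 1024, len(batch)))
            out[idx] = self.net_(batch.take(idx)).data
        return out

    def predict_proba(self, X) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.stack([1.0 - p, p], axis=1)

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


class RetainClassifier(_SequenceClassifier):
    """Bidirectional-LSTM two-level attention network.

    Visit-level (scalar softmax) attention and coordinate-level (tanh)
    gates are combined with the visit embeddings into a context vector;
    age, sex and scaled visit times are concatenated per visit.
    """

    def __init__(self, *, embedding_dim=16, lstm_hidden_dim=16, dropout=0.0,
                 include_static=True, n_concepts=None, max_visits=50, lr=1e-2,
                 batch_size=512, max_epochs=30, early_stop_patience=3,
                 dtype="float32", random_state=0):
        super().__init__(n_concepts=n_concepts, max_visits=max_visits, lr=lr,
                         batch_size=batch_size, max_epochs=max_epochs,
                         early_stop_patience=early_stop_patience,
                         dtype=dtype, random_state=random_state)
        self.embedding_dim = embedding_dim
        self.lstm_hidden_dim = lstm_hidden_dim
        self.dropout = dropout
        self.include_static = include_static

    def _build_net(self, n_concepts: int) -> RetainNet:
        cfg = RetainConfig(embedding_dim=self.embedding_dim,
                           lstm_hidden_dim=self.lstm_hidden_dim,
                           dropout=self.dropout,
                           include_static=self.include_static)
        return RetainNet(n_concepts, cfg, seed=self.random_state)

    def attention(self, X):
        """Per-visit and per-coordinate attention for inspection."""
        from .models_attention import retain_forward

        return retain_forward(self._pack(X), self.net_)


class TransformerClassifier(_SequenceClassifier):
    """Pre-norm multi-head self-attention over visit embeddings with a
    sinusoidal time embedding and a convolutional prediction head."""

    def __init__(self, *, embedding_dim=16, num_heads=2, attn_depth=1,
                 num_hidden=32, dropout=0.0, conv_width=16, head="conv",
                 n_concepts=None, max_visits=50, lr=1e-2, batch_size=512,
                 max_epochs=30, early_stop_patience=3, dtype="float32",
                 random_state=0):
        super().__init__(n_concepts=n_concepts, max_visits=max_visits, lr=lr,
                         batch_size=batch_size, max_epochs=max_epochs,
                         early_stop_patience=early_stop_patience,
                         dtype=dtype, random_state=random_state)
        self.embedding_dim = embedding_dim
        self.num_heads = num_heads
        self.attn_depth = attn_depth
        self.num_hidden = num_hidden
        self.dropout = dropout
        self.conv_width = conv_width
        self.head = head

    def _build_net(self, n_concepts: int) -> TransformerNet:
        cfg = TransformerConfig(embedding_dim=self.embedding_dim,
                                num_heads=self.num_heads,
                                attn_depth=self.attn_depth,
                                num_hidden=self.num_hidden,
                                dropout=self.dropout,
                                conv_width=self.conv_width, head=self.head)
        return TransformerNet(n_concepts, cfg, seed=self.random_state)


class SardClassifier(TransformerClassifier):
    """Transformer with reverse distillation from a linear teacher.

    ``fit`` needs the teacher's logits: distillation matches them on the
    training fold, finetuning blends teacher matching (weight ``alpha``)
    with the label loss on the finetuning fold (the validation fold, as in
    the original recipe — note this reuses the fold later used for
    recalibration).
    """

    def __init__(self, *, alpha=0.5, distill_epochs=10, finetune_epochs=10,
                 distill_lr=None, embedding_dim=16, num_heads=2, attn_depth=1,
                 num_hidden=32,
                 dropout=0.0, conv_width=16, head="conv", n_concepts=None,
                 max_visits=50, lr=1e-2, batch_size=512, max_epochs=30,
                 early_stop_patience=3, dtype="float32", random_state=0):
        super().__init__(embedding_dim=embedding_dim, num_heads=num_heads,
                         attn_depth=attn_depth, num_hidden=num_hidden,
                         dropout=dropout, conv_width=conv_width, head=head,
                         n_concepts=n_concepts, max_visits=max_visits, lr=lr,
                         batch_size=batch_size, max_epochs=max_epochs,
                         early_stop_patience=early_stop_patience,
                         dtype=dtype, random_state=random_state)
        self.alpha = alpha
        self.distill_epochs = distill_epochs
        self.finetune_epochs = finetune_epochs
        self.distill_lr = distill_lr

    def fit(self, X, y, teacher_logits=None, X_val=None, y_val=None,
            teacher_logits_val=None):
        if teacher_logits is None:
            raise ValueError("SardClassifier.fit requires teacher_logits")
        y = np.asarray(y).astype(int)
        self.n_concepts_ = (self.n_concepts if self.n_concepts is not None
                            else _infer_n_concepts(X))
        self.classes_ = np.array([0, 1])
        with _train_dtype(self.dtype):
            self.net_ = self._build_net(self.n_concepts_)
            batch = self._pack(X)
            cfg = self._train_config()
            distill_cfg = (cfg if self.distill_lr is None
                           else self._train_config(lr=self.distill_lr))
            self.distill_history_ = distill(
                self.net_, np.asarray(teacher_logits), batch, distill_cfg,
                epochs=self.distill_epochs)
            if X_val is not None:
                val_batch = self._pack(X_val)
                tl_val = (np.asarray(teacher_logits_val)
                          if teacher_logits_val is not None else None)
                if tl_val is None:
                    raise ValueError("finetuning needs teacher_logits_val")
                self.finetune_history_ = finetune(
                    self.net_, np.asarray(y_val).astype(int), tl_val,
                    self.alpha, val_batch, cfg, epochs=self.finetune_epochs)
            else:
                self.finetune_history_ = finetune(
                    self.net_, y, np.asarray(teacher_logits), self.alpha, batch,
                    cfg, epochs=self.finetune_epochs)
        self.history_ = TrainingHistory(
            train_loss=(self.distill_history_.train_loss
                        + self.finetune_history_.train_loss))
        return self
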