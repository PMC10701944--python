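"""Training machinery: weighted objective, early stopping / LR decay,
reverse distillation and finetuning, hyperparameter search, and refit.

The objective is class-weighted binary cross-entropy with the positive
class weighted by the negative:positive ratio of the training fold (so the
two classes contribute equally in expectation).  Deep models train with
minibatch Adam, early stopping on validation loss with a patience of three
epochs, and a learning-rate reduction by a factor of ten after one stagnant
epoch; the best-validation weights are restored at the end.

Reverse distillation pre-trains a sequence model (the student) to match a
linear teacher's logits by mean squared error, then finetunes with a
mixing factor ``alpha`` blending the teacher-matching term (weight alpha)
and the label loss (weight 1 - alpha); ``alpha=1`` is pure distillation,
``alpha=0`` pure label training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, softplus
from .nn import Adam
from .models_attention import SequenceBatch

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig", "DistillConfig", "TrainingHistory",
    "weighted_bce", "pos_weight_from_labels", "weighted_bce_logits",
    "finetune_loss", "TrainingLoopState", "simulate_schedule",
    "train", "distill", "finetune", "refit_final",
    "tpe_search", "SearchSpace",
]


# -- losses ----------------------------------------------------------------

def pos_weight_from_labels(labels) -> float:
    """Ratio of negative to positive observations."""
    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("labels contain a single class")
    return (len(labels) - n_pos) / n_pos


def weighted_bce(scores, labels, pos_weight: float):
    """Mean of ``-[w*y*log p + (1-y)*log(1-p)]`` over the batch.

    Accepts numpy arrays (returns float) or autodiff Tensors (returns a
    Tensor).  Scores exactly 0 or 1 are clamped at 1e-7.
    """
    if pos_weight <= 0:
        raise ValueError("pos_weight must be positive")
    if isinstance(scores, Tensor):
        y = Tensor(np.asarray(labels, dtype=float))
        eps = 1e-7
        p = scores * (1.0 - 2.0 * eps) + eps  # smooth clamp into (eps, 1-eps)
        loss = -(y * p.log() * pos_weight + (1.0 - y) * (1.0 - p).log())
        return loss.mean()
    p = np.clip(np.asarray(scores, dtype=float), 1e-7, 1.0 - 1e-7)
    y = np.asarray(labels, dtype=float)
    return float(np.mean(-(pos_weight * y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def weighted_bce_logits(logits: Tensor, labels, pos_weight: float) -> Tensor:
    """Numerically stable weighted BCE on logits:
    mean of ``w*y*softplus(-z) + (1-y)*softplus(z)``."""
    y = Tensor(np.asarray(labels, dtype=float))
    loss = y * softplus(-logits) * pos_weight + (1.0 - y) * softplus(logits)
    return loss.mean()


def finetune_loss(logits: Tensor, labels, teacher_logits: np.ndarray,
                  alpha: float, pos_weight: float) -> Tensor:
    """``alpha * MSE(logits, teacher logits) + (1-alpha) * weighted BCE``.

    Exactly linear in alpha at fixed parameters.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    t = Tensor(np.asarray(teacher_logits, dtype=float))
    mse = ((logits - t) ** 2.0).mean()
    bce = weighted_bce_logits(logits, labels, pos_weight)
    return mse * alpha + bce * (1.0 - alpha)


# -- configs ---------------------------------------------------------------

@dataclass
class TrainConfig:
    batch_size: int = 512
    max_epochs: int = 30
    early_stop_patience: int = 3
    lr: float = 1e-3
    lr_reduce_factor: float = 10.0
    lr_reduce_patience: int = 1
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.max_epochs, self.early_stop_patience,
               self.lr_reduce_patience) <= 0 or self.lr <= 0:
            raise ValueError("training configuration values must be positive")


@dataclass
class DistillConfig:
    alpha: float = 0.5
    distill_epochs: int = 10
    finetune_epochs: int = 10

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")


@dataclass
class TrainingHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


# -- early stopping / LR schedule (pure logic, unit-testable) -------------

class TrainingLoopState:
    """Applies the patience rules to a stream of validation losses.

    After each epoch call :meth:`update`; it returns ``True`` when
    training should stop (no improvement for ``early_stop_patience``
    consecutive epochs).  The learning rate is divided by
    ``lr_reduce_factor`` once the loss has stagnated for
    ``lr_reduce_patience`` consecutive epochs (taking effect from the
    next epoch), and the counter resets after each reduction.
    """

    def __init__(self, config: TrainConfig):
        self.config = config
        self.best_loss = np.inf
        self.best_epoch = -1
        self.stall_stop = 0
        self.stall_lr = 0
        self.lr = config.lr

    def update(self, epoch: int, val_loss: float) -> bool:
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = epoch
            self.stall_stop = 0
            self.stall_lr = 0
            return False
        self.stall_stop += 1
        self.stall_lr += 1
        if self.stall_lr >= self.config.lr_reduce_patience:
            self.lr /= self.config.lr_reduce_factor
            self.stall_lr = 0
        return self.stall_stop >= self.config.early_stop_patience


def simulate_schedule(val_losses, config: TrainConfig) -> dict:
    """Replay the early-stop / LR-decay rules on a scripted loss sequence.

    Returns the per-epoch LR trace (the LR in force *during* each epoch),
    the best epoch (1-based) and the epoch after which training stopped
    (or the last epoch if it ran out).
    """
    state = TrainingLoopState(config)
    lr_trace = []
    stopped = len(val_losses)
    for i, loss in enumerate(val_losses):
        lr_trace.append(state.lr)
        if state.update(i + 1, loss):
            stopped = i + 1
            break
    return {"lr_trace": lr_trace, "best_epoch": state.best_epoch,
            "stopped_epoch": stopped}


# -- training loop ---------------------------------------------------------

def _epoch_minibatches(n: int, batch_size: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield idx[start:start + batch_size]


def _eval_loss(model, batch: SequenceBatch, loss_fn, batch_size: int = 1024) -> float:
    model.eval()
    total, n = 0.0, len(batch)
    for start in range(0, n, batch_size):
        sub = batch.take(np.arange(start, min(start + batch_size, n)))
        logits = model(sub)
        total += float(loss_fn(logits, np.arange(start, min(start + batch_size, n))).data) \
            * len(sub)
    model.train()
    return total / n


def train(model, batch: SequenceBatch, labels: np.ndarray, config: TrainConfig,
          val_batch: SequenceBatch | None = None, val_labels: np.ndarray | None = None,
          loss: str = "wbce", teacher_logits: np.ndarray | None = None,
          alpha: float = 0.0, epoch_schedule: list | None = None) -> TrainingHistory:
    """Minibatch Adam with early stopping and LR decay.

    ``loss`` selects the objective: ``"wbce"`` (class-weighted BCE),
    ``"distill"`` (MSE to ``teacher_logits``), or ``"finetune"`` (the
    alpha-blend).  With no validation data (or with ``epoch_schedule``,
    a recorded per-epoch LR list) the loop runs the fixed schedule with no
    monitoring — the refit mode.  Raises on NaN loss.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(config.seed)
    n = len(batch)
    if loss in ("wbce", "finetune"):
        pos_weight = pos_weight_from_labels(labels)
    else:
        pos_weight = 1.0

    def batch_loss(logits, idx):
        if loss == "wbce":
            return weighted_bce_logits(logits, labels[idx], pos_weight)
        if loss == "distill":
            t = Tensor(teacher_logits[idx])
            return ((logits - t) ** 2.0).mean()
        if loss == "finetune":
            return finetune_loss(logits, labels[idx], teacher_logits[idx],
                                 alpha, pos_weight)
        raise ValueError(f"unknown loss {loss!r}")

    def val_loss_fn(logits, pos_idx):
        # pos_idx are positions within the validation fold
        if loss == "wbce":
            return weighted_bce_logits(logits, val_labels[pos_idx], pos_weight)
        if loss == "distill":
            return ((logits - Tensor(teacher_logits[pos_idx])) ** 2.0).mean()
        return finetune_loss(logits, val_labels[pos_idx], teacher_logits[pos_idx],
                             alpha, pos_weight)

    params = model.parameters()
    opt = Adam(params, lr=config.lr)
    state = TrainingLoopState(config)
    history = TrainingHistory()
    best_state = model.state_dict()
    monitored = val_batch is not None and epoch_schedule is None
    n_epochs = len(epoch_schedule) if epoch_schedule is not None else config.max_epochs
    model.train()
    for epoch in range(1, n_epochs + 1):
        opt.lr = epoch_schedule[epoch - 1] if epoch_schedule is not None else state.lr
        ep_loss, n_seen = 0.0, 0
        for idx in _epoch_minibatches(n, config.batch_size, rng):
            sub = batch.take(idx)
            logits = model(sub)
            lval = batch_loss(logits, idx)
            if not np.isfinite(lval.data):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            model.zero_grad()
            lval.backward()
            opt.step()
            ep_loss += float(lval.data) * len(idx)
            n_seen += len(idx)
        history.train_loss.append(ep_loss / n_seen)
        history.lr.append(opt.lr)
        if monitored:
            vloss = _eval_loss(model, val_batch, val_loss_fn)
            history.val_loss.append(vloss)
            improved = vloss < state.best_loss
            stop = state.update(epoch, vloss)
            if improved:
                best_state = model.state_dict()
            if stop:
                history.stopped_epoch = epoch
                break
    if monitored:
        model.load_state_dict(best_state)
        history.best_epoch = state.best_epoch
        if history.stopped_epoch < 0:
            history.stopped_epoch = n_epochs
    return history


def distill_schedule(lr: float, epochs: int) -> list:
    """Step-decay LR schedule for the distillation phase: the teacher-
    matching regression benefits from a high initial rate and two cuts."""
    a = max(1, int(round(0.4 * epochs)))
    b = max(1, int(round(0.35 * epochs)))
    c = max(0, epochs - a - b)
    return [lr] * a + [lr / 3.0] * b + [lr / 10.0] * c


def distill(student, teacher_logits: np.ndarray, batch: SequenceBatch,
            config: TrainConfig, epochs: int | None = None,
            epoch_schedule: list | None = None) -> TrainingHistory:
    """Train the student to reproduce the teacher's logits (MSE).

    Runs a fixed number of epochs (``epochs`` or the config maximum) with
    the step-decay schedule from :func:`distill_schedule` unless an
    explicit per-epoch LR list is given.  Zero epochs leave the student
    unchanged.  Teacher probabilities of exactly 0/1 should be converted
    to logits with clamping upstream.
    """
    if epochs == 0:
        return TrainingHistory()
    n_epochs = epochs or config.max_epochs
    if epoch_schedule is None:
        epoch_schedule = distill_schedule(config.lr, n_epochs)
    return train(student, batch, np.zeros(len(batch)), config,
                 loss="distill",
                 teacher_logits=np.asarray(teacher_logits, dtype=float),
                 epoch_schedule=epoch_schedule)


def finetune(student, labels: np.ndarray, teacher_logits: np.ndarray,
             alpha: float, batch: SequenceBatch, config: TrainConfig,
             epochs: int | None = None) -> TrainingHistory:
    """Blend label loss and teacher matching with mixing factor alpha.

    Zero epochs leave the student unchanged.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    if epochs == 0:
        return TrainingHistory()
    cfg = TrainConfig(**{**config.__dict__,
                         "max_epochs": epochs if epochs is not None
                         else config.max_epochs})
    return train(student, batch, labels, cfg, loss="finetune",
                 teacher_logits=np.asarray(teacher_logits, dtype=float), alpha=alpha)


def refit_final(model, batch: SequenceBatch, labels: np.ndarray,
                config: TrainConfig, epoch_schedule: list) -> TrainingHistory:
    """Refit on the full training data replaying a recorded LR schedule
    (one LR per epoch) with no validation monitoring."""
    return train(model, batch, labels, config, epoch_schedule=list(epoch_schedule))


# -- hyperparameter search -------------------------------------------------

SearchSpace = dict  # name -> ("uniform"|"loguniform"|"int"|"choice", ...)


def _sample_one(rng: np.random.Generator, spec):
    kind = spec[0]
    if kind == "uniform":
        return float(rng.uniform(spec[1], spec[2]))
    if kind == "loguniform":
        return float(np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2]))))
    if kind == "int":
        return int(rng.integers(spec[1], spec[2] + 1))
    if kind == "choice":
        return spec[1][rng.integers(0, len(spec[1]))]
    raise ValueError(f"unknown space kind {kind!r}")


def _tpe_propose(rng: np.random.Generator, spec, good: list, bad: list,
                 n_candidates: int = 24):
    """Per-dimension Parzen proposal: sample candidates from the good-trial
    density, keep the one with the highest good/bad density ratio."""
    kind = spec[0]
    if kind == "choice":
        opts = spec[1]
        counts_g = np.array([1.0 + sum(1 for v in good if v == o) for o in opts])
        counts_b = np.array([1.0 + sum(1 for v in bad if v == o) for o in opts])
        pg = counts_g / counts_g.sum()
        pb = counts_b / counts_b.sum()
        cand = rng.choice(len(opts), size=n_candidates, p=pg)
        best = max(cand, key=lambda i: pg[i] / pb[i])
        return opts[best]
    log_scale = kind == "loguniform"
    lo, hi = spec[1], spec[2]
    to_u = (lambda v: np.log(v)) if log_scale else (lambda v: float(v))
    from_u = (lambda u: float(np.exp(u))) if log_scale else (lambda u: float(u))
    ulo, uhi = to_u(lo), to_u(hi)
    width = uhi - ulo

    def density(u, pts):
        if not pts:
            return np.full_like(u, 1.0 / width)
        pts = np.asarray(pts)
        bw = max(width / max(len(pts), 1), width / 20.0)
        d = np.exp(-0.5 * ((u[:, None] - pts[None, :]) / bw) ** 2).sum(axis=1)
        return (d / (len(pts) * bw * np.sqrt(2 * np.pi))) + 1e-12

    gpts = [to_u(v) for v in good]
    bpts = [to_u(v) for v in bad]
    if gpts:
        centers = rng.choice(len(gpts), size=n_candidates)
        bw = max(width / max(len(gpts), 1), width / 20.0)
        cand = np.clip(np.array([gpts[c] for c in centers])
                       + rng.normal(0, bw, size=n_candidates), ulo, uhi)
    else:
        cand = rng.uniform(ulo, uhi, size=n_candidates)
    score = density(cand, gpts) / density(cand, bpts)
    u = cand[int(np.argmax(score))]
    val = from_u(u)
    if kind == "int":
        val = int(np.clip(round(val), lo, hi))
    return val


def tpe_search(space: SearchSpace, objective, n_iter: int = 20, seed: int = 0,
               backend: str = "tpe", n_startup: int = 10, gamma: float = 0.25):
    """Maximize ``objective(config)`` over the space.

    A lightweight tree-of-Parzen-estimators: after ``n_startup`` random
    trials, trials are split at the ``gamma`` quantile of the objective
    and new candidates are drawn from a Parzen density over the good
    trials, scored by the good/bad density ratio (per dimension,
    independently).  ``backend="random"`` falls back to pure random
    search.  Failing configurations are logged and skipped.  Returns
    ``(best_config, trial_log)`` with the trial log a list of
    ``{"config": ..., "value": ...}`` rows (value ``None`` on failure).
    """
    rng = np.random.default_rng(seed)
    trials: list[dict] = []
    for it in range(n_iter):
        ok_trials = [t for t in trials if t["value"] is not None]
        if backend == "random" or it < n_startup or len(ok_trials) < 4:
            config = {k: _sample_one(rng, spec) for k, spec in space.items()}
        else:
            vals = np.array([t["value"] for t in ok_trials])
            cut = np.quantile(vals, 1.0 - gamma)
            good = [t for t in ok_trials if t["value"] >= cut]
            bad = [t for t in ok_trials if t["value"] < cut] or ok_trials
            config = {k: _tpe_propose(rng, spec,
                                      [t["config"][k] for t in good],
                                      [t["config"][k] for t in bad])
                      for k, spec in space.items()}
        try:
            value = float(objective(config))
        except Exception as exc:  # noqa: BLE001 - search must survive bad configs
            logger.warning("trial failed for %s: %s", config, exc)
            value = None
        trials.append({"config": config, "value": value})
    ok_trials = [t for t in trials if t["value"] is not None]
    if not ok_trials:
        raise RuntimeError("every trial failed")
    best = max(ok_trials, key=lambda t: t["value"])
    return best["config"], trials
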