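"""Objective closed forms, scheduler rules, distillation/finetuning
identities, hyperparameter search behaviour."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from attnrisk.autodiff import Tensor
from attnrisk.models_attention import TransformerConfig, TransformerNet
from attnrisk.training import (TrainConfig, distill, finetune, finetune_loss,
                               pos_weight_from_labels, refit_final,
                               simulate_schedule, tpe_search, train,
                               weighted_bce, weighted_bce_logits)


# -- weighted BCE ----------------------------------------------------------

def test_pos_weight_is_neg_over_pos_ratio():
    labels = np.r_[np.ones(1), np.zeros(99)]
    assert pos_weight_from_labels(labels) == pytest.approx(99.0)
    with pytest.raises(ValueError):
        pos_weight_from_labels(np.ones(5))


def test_weighted_bce_closed_forms():
    # single case at p = 0.5 with weight 2: loss = 2 ln 2
    assert weighted_bce(np.array([0.5]), np.array([1]), 2.0) == \
        pytest.approx(2 * np.log(2))
    # perfect predictions: loss at the clamp scale
    assert weighted_bce(np.array([1.0, 0.0]), np.array([1, 0]), 3.0) < 1e-5
    with pytest.raises(ValueError):
        weighted_bce(np.array([0.5]), np.array([1]), 0.0)


def test_weighted_bce_weight_one_is_plain_bce():
    rng = np.random.default_rng(0)
    for _ in range(10):
        p = rng.uniform(0.01, 0.99, 50)
        y = rng.integers(0, 2, 50)
        plain = float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))
        assert weighted_bce(p, y, 1.0) == pytest.approx(plain, abs=1e-12)


def test_weighted_bce_tensor_and_logits_agree():
    rng = np.random.default_rng(1)
    z = rng.normal(size=40)
    y = rng.integers(0, 2, 40)
    p = 1 / (1 + np.exp(-z))
    a = weighted_bce(p, y, 7.0)
    b = float(weighted_bce(Tensor(p), y, 7.0).data)
    c = float(weighted_bce_logits(Tensor(z), y, 7.0).data)
    assert a == pytest.approx(b, abs=1e-6)
    assert a == pytest.approx(c, abs=1e-6)


# -- scheduler rules -------------------------------------------------------

def test_early_stop_patience_three():
    cfg = TrainConfig(lr=1e-2)
    out = simulate_schedule([1.0, 0.9, 0.95, 0.96, 0.97], cfg)
    assert out["stopped_epoch"] == 5
    assert out["best_epoch"] == 2


def test_strictly_decreasing_runs_to_max():
    cfg = TrainConfig(lr=1e-2, max_epochs=6)
    out = simulate_schedule([1.0, 0.9, 0.8, 0.7, 0.6, 0.5], cfg)
    assert out["stopped_epoch"] == 6 and out["best_epoch"] == 6
    assert out["lr_trace"] == [1e-2] * 6


def test_lr_drops_tenfold_from_epoch_three():
    cfg = TrainConfig(lr=1e-2)
    out = simulate_schedule([1.0, 1.1, 1.2, 1.3], cfg)
    assert out["lr_trace"] == pytest.approx([1e-2, 1e-2, 1e-3, 1e-4])
    assert out["stopped_epoch"] == 4  # three stagnant epochs after epoch 1


def test_improvement_resets_both_counters():
    cfg = TrainConfig(lr=1e-2)
    out = simulate_schedule([1.0, 1.1, 0.8, 0.9, 0.95, 0.99], cfg)
    # epoch 3 improves: stop counter resets, but the LR cut (after epoch 2)
    # has already taken effect
    assert out["stopped_epoch"] == 6
    assert out["best_epoch"] == 3
    assert out["lr_trace"][:4] == pytest.approx([1e-2, 1e-2, 1e-3, 1e-3])


# -- training loop on a real model ----------------------------------------

def _tiny_net(n_concepts, seed=0):
    return TransformerNet(n_concepts, TransformerConfig(
        embedding_dim=8, num_heads=2, num_hidden=16, conv_width=8), seed=seed)


def test_overfit_memorization_fixture(memorization_batch):
    """Both architectures drive weighted-BCE training loss below 0.05 on a
    64-observation fixture within 500 steps."""
    from attnrisk.models_attention import RetainConfig, RetainNet

    seqs, batch, labels, n_concepts = memorization_batch
    for net in (_tiny_net(n_concepts, seed=1),
                RetainNet(n_concepts, RetainConfig(embedding_dim=8,
                                                   lstm_hidden_dim=8), seed=1)):
        cfg = TrainConfig(batch_size=64, max_epochs=500, lr=3e-2, seed=0)
        hist = train(net, batch, labels, cfg)
        pw = pos_weight_from_labels(labels)
        net.eval()
        final = float(weighted_bce_logits(net(batch), labels, pw).data)
        assert final < 0.05, type(net).__name__


def test_train_restores_best_weights(memorization_batch):
    seqs, batch, labels, n_concepts = memorization_batch
    net = _tiny_net(n_concepts, seed=2)
    cfg = TrainConfig(batch_size=32, max_epochs=15, lr=5e-2, seed=0)
    hist = train(net, batch, labels, cfg, val_batch=batch, val_labels=labels)
    assert hist.best_epoch >= 1
    pw = pos_weight_from_labels(labels)
    net.eval()
    final = float(weighted_bce_logits(net(batch), labels, pw).data)
    assert final == pytest.approx(min(hist.val_loss), abs=1e-9)


def test_distill_matches_teacher(memorization_batch):
    seqs, batch, labels, n_concepts = memorization_batch
    rng = np.random.default_rng(3)
    teacher_logits = rng.normal(0, 1.5, len(batch))
    net = _tiny_net(n_concepts, seed=3)
    cfg = TrainConfig(batch_size=64, max_epochs=400, lr=3e-2, seed=0)
    distill(net, teacher_logits, batch, cfg)
    net.eval()
    rho = spearmanr(net(batch).data, teacher_logits).statistic
    assert rho >= 0.95


def test_zero_epoch_distillation_is_identity(memorization_batch):
    seqs, batch, labels, n_concepts = memorization_batch
    net = _tiny_net(n_concepts, seed=4)
    before = {k: v.copy() for k, v in net.state_dict().items()}
    distill(net, np.zeros(len(batch)), batch, TrainConfig(lr=1e-2), epochs=0)
    for k, v in net.state_dict().items():
        np.testing.assert_array_equal(v, before[k])


def test_constant_teacher_shrinks_logit_variance(memorization_batch):
    seqs, batch, labels, n_concepts = memorization_batch
    net = _tiny_net(n_concepts, seed=5)
    net.eval()
    v0 = float(np.var(net(batch).data))
    net.train()
    distill(net, np.full(len(batch), 0.7), batch,
            TrainConfig(batch_size=64, lr=2e-2, seed=0), epochs=150)
    net.eval()
    out = net(batch).data
    assert float(np.var(out)) < 0.1 * max(v0, 1e-6) or float(np.var(out)) < 1e-4
    assert np.mean(out) == pytest.approx(0.7, abs=0.1)


def test_finetune_loss_linear_in_alpha():
    rng = np.random.default_rng(6)
    z = Tensor(rng.normal(size=30))
    y = rng.integers(0, 2, 30)
    t = rng.normal(size=30)
    losses = {a: float(finetune_loss(z, y, t, a, 3.0).data)
              for a in (0.0, 0.25, 0.5, 1.0)}
    l0, l1 = losses[0.0], losses[1.0]
    assert losses[0.25] == pytest.approx(0.25 * l1 + 0.75 * l0, abs=1e-12)
    assert losses[0.5] == pytest.approx(0.5 * (l0 + l1), abs=1e-12)
    # alpha = 0 is exactly the weighted label loss
    assert l0 == pytest.approx(float(weighted_bce_logits(z, y, 3.0).data),
                               abs=1e-15)
    with pytest.raises(ValueError):
        finetune_loss(z, y, t, 1.5, 3.0)


def test_finetune_alpha_one_tracks_teacher(memorization_batch):
    seqs, batch, labels, n_concepts = memorization_batch
    rng = np.random.default_rng(7)
    teacher_logits = rng.normal(0, 1.5, len(batch))
    net = _tiny_net(n_concepts, seed=6)
    finetune(net, labels, teacher_logits, 1.0, batch,
             TrainConfig(batch_size=64, lr=1e-2, seed=0), epochs=800)
    net.eval()
    rho = spearmanr(net(batch).data, teacher_logits).statistic
    assert rho >= 0.95


def test_refit_replays_schedule(memorization_batch):
    seqs, batch, labels, n_concepts = memorization_batch
    schedule = [1e-2, 1e-2, 1e-3]
    nets = []
    for _ in range(2):
        net = _tiny_net(n_concepts, seed=8)
        hist = refit_final(net, batch, labels,
                           TrainConfig(batch_size=64, lr=1e-2, seed=0), schedule)
        assert hist.lr == schedule and len(hist.train_loss) == 3
        nets.append(net)
    # deterministic under seed: two replays give identical weights
    for (k, a), (_, b) in zip(nets[0].state_dict().items(),
                              nets[1].state_dict().items()):
        np.testing.assert_array_equal(a, b)
    net = _tiny_net(n_concepts, seed=8)
    hist = refit_final(net, batch, labels,
                       TrainConfig(batch_size=64, lr=1e-2, seed=0),
                       [1e-2] * 20)
    assert hist.train_loss[-1] <= hist.train_loss[0]


# -- hyperparameter search -------------------------------------------------

def test_tpe_single_point_space():
    best, log = tpe_search({"lr": ("choice", [0.1])},
                           lambda c: 0.8, n_iter=1, seed=0)
    assert best == {"lr": 0.1} and len(log) == 1
    ok = [t["value"] for t in log if t["value"] is not None]
    assert max(ok) == 0.8


def test_tpe_best_equals_log_max():
    rng = np.random.default_rng(8)
    best, log = tpe_search({"x": ("uniform", 0.0, 1.0)},
                           lambda c: np.sin(7 * c["x"]), n_iter=15, seed=1)
    vals = [t["value"] for t in log if t["value"] is not None]
    assert np.sin(7 * best["x"]) == pytest.approx(max(vals))


def test_tpe_beats_random_scan_decile_on_quadratic():
    def objective(c):
        return -(c["x"] - 0.3) ** 2

    best, log = tpe_search({"x": ("uniform", 0.0, 1.0)}, objective,
                           n_iter=30, seed=2)
    rng = np.random.default_rng(1234)
    scan = -(rng.uniform(0, 1, 1000) - 0.3) ** 2
    assert objective(best) >= np.quantile(scan, 0.9)


def test_tpe_survives_failing_trials():
    def objective(c):
        if c["x"] < 0.5:
            raise RuntimeError("boom")
        return c["x"]

    best, log = tpe_search({"x": ("uniform", 0.0, 1.0)}, objective,
                           n_iter=20, seed=3)
    assert best["x"] >= 0.5
    assert any(t["value"] is None for t in log)


def test_tpe_random_backend_and_int_choice_dims():
    space = {"lr": ("loguniform", 1e-4, 1e-1), "depth": ("int", 1, 4),
             "head": ("choice", [2, 4])}
    best, log = tpe_search(space, lambda c: -c["lr"], n_iter=12, seed=4,
                           backend="random")
    assert 1e-4 <= best["lr"] <= 1e-1
    assert best["depth"] in (1, 2, 3, 4) and best["head"] in (2, 4)
    best2, _ = tpe_search(space, lambda c: c["depth"] + c["head"], n_iter=25,
                          seed=5)
    assert best2["depth"] == 4 and best2["head"] == 4
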