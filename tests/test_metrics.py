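"""Metric oracles: pair counting, structural-components DeLong variance,
hand-enumerated precision-recall, Platt identities, spline calibration,
confusion-matrix net benefit, Shapley additivity."""

import numpy as np
import pytest
from scipy.special import expit, logit

from attnrisk.metrics import (MetricWithCI, Predictions,
                              auc_ci, auprc, auprc_ci, delong_auc_variance,
                              hyperparam_importance, net_benefit, platt_apply,
                              platt_fit, rcs_basis, roc_auc, smooth_calibration)


def brute_force_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def delong_structural_oracle(scores, labels):
    """O(m*n) definition: variance from per-observation structural components."""
    pos = scores[labels == 1]
    neg = scores[labels != 1]
    m, n = len(pos), len(neg)
    psi = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    v_cases = psi.mean(axis=1)
    v_controls = psi.mean(axis=0)
    auc = psi.mean()
    return auc, (np.var(v_cases, ddof=1) / m + np.var(v_controls, ddof=1) / n)


# -- discrimination --------------------------------------------------------

def test_roc_auc_worked_example():
    assert roc_auc(np.array([.9, .8, .7, .6]), np.array([1, 0, 1, 0])) == 0.75


def test_roc_auc_edge_conventions():
    assert roc_auc(np.array([.9, .8, .2, .1]), np.array([1, 1, 0, 0])) == 1.0
    assert roc_auc(np.full(6, .5), np.array([1, 0, 1, 0, 1, 0])) == 0.5
    with pytest.raises(ValueError):
        roc_auc(np.array([.5, .6]), np.array([1, 1]))


def test_roc_auc_matches_pair_counting_oracle():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = rng.integers(10, 200)
        scores = np.round(rng.random(n), 2)  # force ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            continue
        assert roc_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12)


def test_delong_variance_matches_structural_oracle():
    rng = np.random.default_rng(1)
    for _ in range(25):
        n = rng.integers(10, 50)
        scores = np.round(rng.random(n), 1)
        labels = rng.integers(0, 2, n)
        if labels.sum() < 2 or labels.sum() > n - 2:
            continue
        auc, var = delong_auc_variance(scores, labels)
        auc_o, var_o = delong_structural_oracle(scores, labels)
        assert auc == pytest.approx(auc_o, abs=1e-12)
        assert var == pytest.approx(var_o, rel=1e-10, abs=1e-14)


def test_auc_ci_clipped_at_one():
    pred = Predictions(np.array([.9, .8, .2, .1]), np.array([1, 1, 0, 0]))
    ci = auc_ci(pred)
    assert ci.upper == 1.0 and ci.estimate == 1.0


def test_auprc_hand_enumeration():
    # ranked: .9(+) .8(-) .7(+) .6(-): AP = 1*0.5 + (2/3)*0.5
    pred = Predictions(np.array([.9, .8, .7, .6]), np.array([1, 0, 1, 0]))
    assert auprc(pred) == pytest.approx(0.5 + 1 / 3, abs=1e-12)
    perfect = Predictions(np.array([.9, .8, .2, .1]), np.array([1, 1, 0, 0]))
    assert auprc(perfect) == 1.0


def test_auprc_null_limit_is_prevalence():
    rng = np.random.default_rng(2)
    n, pi = 20_000, 0.15
    labels = (rng.random(n) < pi).astype(int)
    pred = Predictions(rng.random(n), labels)
    assert auprc(pred) == pytest.approx(labels.mean(), abs=0.02)


def test_auprc_ci_brackets_and_bootstrap_agrees():
    rng = np.random.default_rng(3)
    labels = rng.integers(0, 2, 500)
    scores = np.clip(labels * 0.3 + rng.random(500) * 0.7, 0, 1)
    pred = Predictions(scores, labels)
    ci = auprc_ci(pred)
    assert 0 <= ci.lower <= ci.estimate <= ci.upper <= 1
    boot = auprc_ci(pred, method="bootstrap", n_boot=200, seed=0)
    assert abs(boot.lower - ci.lower) < 0.1


# -- Platt recalibration ---------------------------------------------------

def _calibrated_scores(n, rng):
    p = rng.uniform(0.02, 0.4, n)
    y = (rng.random(n) < p).astype(int)
    return p, y


def test_platt_recovers_identity_on_calibrated_scores():
    rng = np.random.default_rng(4)
    p, y = _calibrated_scores(20_000, rng)
    params = platt_fit(Predictions(p, y))
    assert abs(params.slope - 1) < 0.1
    assert abs(params.intercept) < 0.1


def test_platt_recovers_known_shift():
    rng = np.random.default_rng(5)
    p, y = _calibrated_scores(20_000, rng)
    shifted = expit(logit(p) + 2.0)
    params = platt_fit(Predictions(shifted, y))
    assert params.intercept == pytest.approx(-2.0, abs=0.15)
    assert params.slope == pytest.approx(1.0, abs=0.1)


def test_platt_mean_score_equals_event_rate_on_fitting_fold():
    rng = np.random.default_rng(6)
    p, y = _calibrated_scores(5_000, rng)
    overconfident = expit(3 * logit(p) + 1)
    pred = Predictions(overconfident, y)
    params = platt_fit(pred)
    recal = platt_apply(pred.scores, params)
    assert recal.mean() == pytest.approx(y.mean(), abs=1e-6)


def test_platt_identity_application_and_rank_preservation():
    rng = np.random.default_rng(7)
    scores = rng.random(200)
    labels = rng.integers(0, 2, 200)
    from attnrisk.metrics import RecalibrationParams

    np.testing.assert_allclose(
        platt_apply(scores, RecalibrationParams(1.0, 0.0)), scores, atol=1e-9)
    params = RecalibrationParams(2.5, -1.0)
    assert roc_auc(platt_apply(scores, params), labels) == \
        pytest.approx(roc_auc(scores, labels), abs=1e-12)


def test_platt_idempotent_in_distribution():
    rng = np.random.default_rng(8)
    p, y = _calibrated_scores(20_000, rng)
    miscal = expit(2 * logit(p) - 1)
    pred = Predictions(miscal, y)
    once = platt_apply(pred.scores, platt_fit(pred))
    again = platt_fit(Predictions(once, y))
    assert abs(again.slope - 1) < 0.05 and abs(again.intercept) < 0.05


def test_platt_constant_scores_intercept_only():
    pred = Predictions(np.full(100, 0.3), np.r_[np.ones(20), np.zeros(80)].astype(int))
    with pytest.warns(UserWarning):
        params = platt_fit(pred)
    recal = platt_apply(pred.scores, params)
    assert recal.mean() == pytest.approx(0.2, abs=1e-9)


# -- smooth calibration ----------------------------------------------------

def test_rcs_basis_linear_tails_and_span():
    knots = np.array([-2.0, -0.5, 0.0, 0.5, 2.0])
    x = np.linspace(-6, 6, 400)
    B = rcs_basis(x, knots)
    # linear functions lie in the span (the first column is x itself)
    target = 2.0 * x + 1.0
    coef, res, *_ = np.linalg.lstsq(np.c_[np.ones_like(x), B], target, rcond=None)
    assert np.abs(np.c_[np.ones_like(x), B] @ coef - target).max() < 1e-8
    # beyond the boundary knots each basis column is linear in x
    left = x < -2
    for j in range(B.shape[1]):
        d2 = np.diff(B[left, j], 2)
        assert np.abs(d2).max() < 1e-8


def test_smooth_calibration_near_diagonal_when_calibrated():
    rng = np.random.default_rng(9)
    p = rng.uniform(0.02, 0.5, 20_000)
    y = (rng.random(20_000) < p).astype(int)
    curve = smooth_calibration(Predictions(p, y))
    lo, hi = np.quantile(p, [0.05, 0.95])
    central = (curve.grid >= lo) & (curve.grid <= hi)
    assert np.abs(curve.observed[central] - curve.grid[central]).max() < 0.05


def test_smooth_calibration_constant_scores():
    y = np.r_[np.ones(30), np.zeros(70)].astype(int)
    curve = smooth_calibration(Predictions(np.full(100, 0.6), y))
    np.testing.assert_allclose(curve.observed, 0.3)


# -- decision curves -------------------------------------------------------

def test_net_benefit_perfect_classifier():
    labels = np.r_[np.ones(20), np.zeros(80)].astype(int)
    scores = labels * 0.9 + 0.05
    dc = net_benefit(Predictions(scores, labels), np.array([0.1, 0.3, 0.5]))
    np.testing.assert_allclose(dc.nb_model, 0.2, atol=1e-12)
    np.testing.assert_allclose(dc.nb_treat_none, 0.0)


def test_net_benefit_treat_all_closed_form():
    labels = np.r_[np.ones(20), np.zeros(80)].astype(int)
    dc = net_benefit(Predictions(np.full(100, .5), labels), np.array([0.5]))
    assert dc.nb_treat_all[0] == pytest.approx(0.2 - 0.8 * 1.0)


def test_net_benefit_counting_oracle_ten_rows():
    scores = np.array([.05, .12, .22, .28, .33, .41, .55, .62, .74, .91])
    labels = np.array([0, 0, 1, 0, 0, 1, 0, 1, 1, 1])
    t = 0.3
    pred_pos = scores >= t
    tp = int(np.sum(pred_pos & (labels == 1)))    # 4
    fp = int(np.sum(pred_pos & (labels == 0)))    # 2
    expected = tp / 10 - fp / 10 * t / (1 - t)
    dc = net_benefit(Predictions(scores, labels), np.array([t]))
    assert dc.nb_model[0] == pytest.approx(expected, abs=1e-12)
    assert tp == 4 and fp == 2


def test_net_benefit_bounds_and_crossing():
    rng = np.random.default_rng(10)
    labels = rng.integers(0, 2, 500)
    scores = np.clip(0.3 * labels + rng.random(500) * 0.6, 0, 1)
    pred = Predictions(scores, labels)
    dc = net_benefit(pred)
    pi = labels.mean()
    assert np.all(dc.nb_model <= pi + 1e-12)
    # treat-all crosses zero exactly at t = prevalence
    t_cross = dc.thresholds[np.argmin(np.abs(dc.nb_treat_all))]
    assert abs(t_cross - pi) < 0.002
    with pytest.raises(ValueError):
        net_benefit(pred, np.array([1.0]))


# -- hyperparameter importance --------------------------------------------

def _toy_trials(n=30, seed=0, informative=True):
    import pandas as pd

    rng = np.random.default_rng(seed)
    lr = rng.uniform(-4, -1, n)
    depth = rng.integers(1, 5, n).astype(float)
    drop = rng.uniform(0, 0.5, n)
    auc = 0.75 - (informative * 0.05) * (lr + 2.5) ** 2 + 0.001 * rng.normal(size=n)
    return pd.DataFrame({"lr": lr, "attn_depth": depth, "dropout": drop,
                         "val_auc": auc})


def test_shapley_additivity():
    trials = _toy_trials()
    res = hyperparam_importance(trials, seed=0)
    from sklearn.ensemble import RandomForestRegressor

    rf = RandomForestRegressor(n_estimators=200, random_state=0)
    feats = ["lr", "attn_depth", "dropout"]
    rf.fit(trials[feats].to_numpy(), trials["val_auc"].to_numpy())
    pred = rf.predict(trials[feats].to_numpy())
    attr = res["attributions"].pivot_table(index="trial", values="attribution",
                                           columns="hyperparameter", sort=False)
    totals = attr.sum(axis=1).to_numpy() + res["base_value"]
    np.testing.assert_allclose(totals, pred, atol=1e-6)


def test_constant_outcome_gives_zero_attributions():
    trials = _toy_trials(informative=False)
    trials["val_auc"] = 0.7
    res = hyperparam_importance(trials)
    assert np.abs(res["attributions"]["attribution"]).max() < 1e-12


def test_planted_dependence_ranked_first():
    res = hyperparam_importance(_toy_trials())
    assert res["summary"].iloc[0]["hyperparameter"] == "lr"
    with pytest.raises(ValueError):
        hyperparam_importance(_toy_trials(n=5))


# -- containers ------------------------------------------------------------

def test_predictions_validation():
    with pytest.raises(ValueError):
        Predictions(np.array([0.5, 1.2]), np.array([0, 1]))
    with pytest.raises(ValueError):
        Predictions(np.array([0.5]), np.array([0, 1]))
    with pytest.raises(ValueError):
        MetricWithCI(0.5, 0.6, 0.7)
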