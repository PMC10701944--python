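"""Evaluation suite: discrimination, recalibration, calibration curves,
decision-curve analysis, and hyperparameter importance.

Conventions

* AUC is the Mann-Whitney probability that a random case outscores a
  random control, ties counted 1/2; its confidence interval uses the
  DeLong variance computed with the fast midrank algorithm.
* AUPRC is average precision (step-wise, no interpolation), with a
  logit-scale normal interval.
* Recalibration is Platt scaling on the logit scale: ``sigmoid(a *
  logit(p) + b)`` with (a, b) fit by maximum likelihood on a held-out
  fold.  Models trained with class-weighted objectives overestimate risk
  by construction and need this step.
* Smooth calibration curves regress the outcome on a restricted cubic
  spline basis of logit(predicted risk) with logistic link.
* Net benefit at threshold t is ``TP/N - FP/N * t/(1-t)`` for the policy
  "treat if score >= t", compared with treat-all and treat-none.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit as _logit

EPS = 1e-7


def _clip_probs(p: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(p, dtype=float), EPS, 1.0 - EPS)


@dataclass
class Predictions:
    """Paired risk scores in [0,1] and binary labels."""

    scores: np.ndarray
    labels: np.ndarray
    fold: str = ""

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have equal length")
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValueError("scores must lie in [0, 1]")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary")


@dataclass
class MetricWithCI:
    estimate: float
    lower: float
    upper: float
    level: float = 0.95
    method: str = ""

    def __post_init__(self):
        if not (self.lower <= self.estimate <= self.upper):
            raise ValueError("CI must bracket the estimate")


# -- discrimination --------------------------------------------------------

def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_auc_variance(scores, labels) -> tuple[float, float]:
    """AUC and its DeLong variance via the fast midrank algorithm."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    pos = scores[labels == 1]
    neg = scores[labels != 1]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n            # structural components of the cases
    v10 = 1.0 - (tz[m:] - ty) / m      # structural components of the controls
    s01 = np.var(v01, ddof=1) if m > 1 else 0.0
    s10 = np.var(v10, ddof=1) if n > 1 else 0.0
    return float(auc), float(s01 / m + s10 / n)


def auc_ci(pred: Predictions, level: float = 0.95) -> MetricWithCI:
    """Normal-approximation CI with the DeLong variance, clipped to [0,1]."""
    auc, var = delong_auc_variance(pred.scores, pred.labels)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return MetricWithCI(estimate=auc, lower=max(0.0, auc - half),
                        upper=min(1.0, auc + half), level=level, method="delong")


def auprc(pred: Predictions) -> float:
    """Average precision (step-wise area under the precision-recall curve)."""
    from sklearn.metrics import average_precision_score

    _check_two_classes(pred.labels)
    return float(average_precision_score(pred.labels, pred.scores))


def auprc_ci(pred: Predictions, level: float = 0.95,
             method: str = "logit", n_boot: int = 1000, seed: int = 0) -> MetricWithCI:
    """Logit-scale normal interval for average precision (bootstrap optional).

    The default uses the logit interval with standard error
    ``1 / sqrt(n_pos * ap * (1 - ap))``, which respects the [0,1] range;
    ``method="bootstrap"`` resamples observations instead.
    """
    ap = auprc(pred)
    n_pos = int(pred.labels.sum())
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = len(pred.labels)
        vals = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            if pred.labels[idx].min() == pred.labels[idx].max():
                continue
            vals.append(auprc(Predictions(pred.scores[idx], pred.labels[idx])))
        lo, hi = np.quantile(vals, [(1 - level) / 2, 0.5 + level / 2])
        return MetricWithCI(ap, float(min(lo, ap)), float(max(hi, ap)), level, "bootstrap")
    apc = float(np.clip(ap, EPS, 1 - EPS))
    se = 1.0 / np.sqrt(max(n_pos, 1) * apc * (1.0 - apc))
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo = float(expit(_logit(apc) - z * se))
    hi = float(expit(_logit(apc) + z * se))
    return MetricWithCI(ap, min(lo, ap), max(hi, ap), level, "logit")


# -- recalibration ---------------------------------------------------------

@dataclass
class RecalibrationParams:
    slope: float
    intercept: float

    def __post_init__(self):
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("recalibration parameters must be finite")


def platt_fit(pred: Predictions) -> RecalibrationParams:
    """Fit ``sigmoid(a * logit(p) + b)`` by maximum likelihood.

    On the fitting fold the logistic score equations make the mean
    recalibrated score equal the event rate.  Constant scores leave the
    slope unidentifiable; an intercept-only model is fit instead.
    """
    import statsmodels.api as sm

    x = _logit(_clip_probs(pred.scores))
    y = pred.labels
    if np.ptp(x) < 1e-12:
        import warnings

        warnings.warn("constant scores: slope unidentifiable, fitting intercept only")
        b = _logit(np.clip(y.mean(), EPS, 1 - EPS)) - x[0]
        return RecalibrationParams(slope=1.0, intercept=float(b))
    X = sm.add_constant(x)
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(tol=1e-10, maxiter=200)
        b, a = res.params
    except Exception:  # separation etc.: fall back to a ridge-stabilized fit
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(alpha=1e-6)
        b, a = res.params
    return RecalibrationParams(slope=float(a), intercept=float(b))


def platt_apply(scores, params: RecalibrationParams) -> np.ndarray:
    z = _logit(_clip_probs(scores))
    return expit(params.slope * z + params.intercept)


# -- smooth calibration ----------------------------------------------------

HARRELL_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.1833, 0.3417, 0.5, 0.6583, 0.8167, 0.975),
}


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (linear tails): columns [x, s_1..s_{k-2}]."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = len(t)
    if k < 3:
        return x[:, None]
    norm = (t[-1] - t[0]) ** 2

    def plus3(v):
        return np.clip(v, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (plus3(x - t[j])
                - plus3(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
                + plus3(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2]))
        cols.append(term / norm)
    return np.stack(cols, axis=1)


@dataclass
class CalibrationCurve:
    grid: np.ndarray           # predicted risk
    observed: np.ndarray       # spline-smoothed observed risk
    lower: np.ndarray
    upper: np.ndarray
    knots: np.ndarray          # on the logit scale
    density_quantiles: dict = field(default_factory=dict)


def smooth_calibration(pred: Predictions, n_knots: int = 5,
                       n_grid: int = 100) -> CalibrationCurve:
    """Logistic regression of outcome on an RCS basis of logit(score).

    Knots sit at Harrell's standard quantiles of the logit-scores.  The
    curve is evaluated on an even grid between the 1st and 99th score
    percentiles; a density summary (score quantiles) is attached so plots
    can show where predictions actually live.
    """
    import statsmodels.api as sm
    import warnings

    x = _logit(_clip_probs(pred.scores))
    n_distinct = len(np.unique(x))
    if n_distinct < 3:  # (near-)constant scores: flat curve at the event rate
        rate = float(pred.labels.mean())
        grid = np.unique(pred.scores)
        flat = np.full_like(grid, rate, dtype=float)
        return CalibrationCurve(grid=grid, observed=flat, lower=flat, upper=flat,
                                knots=np.unique(x),
                                density_quantiles={"q50": float(np.median(pred.scores))})
    while n_knots > 3 and n_distinct < n_knots + 2:
        warnings.warn("few distinct scores: reducing knot count")
        n_knots -= 1
    qs = HARRELL_KNOT_QUANTILES.get(n_knots)
    if qs is None:
        qs = tuple(np.linspace(0.05, 0.95, n_knots))
    knots = np.unique(np.quantile(x, qs))
    B = sm.add_constant(rcs_basis(x, knots))
    model = sm.GLM(pred.labels, B, family=sm.families.Binomial())
    try:
        res = model.fit(tol=1e-10, maxiter=200)
    except Exception:
        res = model.fit_regularized(alpha=1e-6)
    lo_s, hi_s = np.quantile(pred.scores, [0.01, 0.99])
    grid_p = np.linspace(max(lo_s, EPS), min(hi_s, 1 - EPS), n_grid)
    Bg = sm.add_constant(rcs_basis(_logit(grid_p), knots), has_constant="add")
    eta = Bg @ res.params
    obs = expit(eta)
    try:
        cov = res.cov_params()
        se = np.sqrt(np.einsum("ij,jk,ik->i", Bg, cov, Bg))
    except Exception:
        se = np.zeros_like(eta)
    dq = {f"q{int(q * 100):02d}": float(np.quantile(pred.scores, q))
          for q in (0.05, 0.25, 0.5, 0.75, 0.95)}
    return CalibrationCurve(
        grid=grid_p, observed=obs,
        lower=expit(eta - 1.96 * se), upper=expit(eta + 1.96 * se),
        knots=knots, density_quantiles=dq)


# -- decision curves -------------------------------------------------------

@dataclass
class DecisionCurve:
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_treat_all: np.ndarray
    nb_treat_none: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds, "net_benefit": self.nb_model,
            "treat_all": self.nb_treat_all, "treat_none": self.nb_treat_none})


def net_benefit(pred: Predictions, thresholds: np.ndarray | None = None) -> DecisionCurve:
    """NB(t) = TP(t)/N - FP(t)/N * t/(1-t), classifying score >= t as high
    risk; treat-all = pi - (1-pi) * t/(1-t); treat-none = 0."""
    if thresholds is None:
        thresholds = np.arange(0.001, 0.5 + 1e-12, 0.001)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds >= 1.0) or np.any(thresholds <= 0.0):
        raise ValueError("thresholds must lie in (0, 1)")
    n = len(pred.labels)
    pi = pred.labels.mean()
    order = np.argsort(pred.scores)
    sorted_scores = pred.scores[order]
    sorted_labels = pred.labels[order]
    # cumulative positives/negatives with score >= t via searchsorted
    cum_pos_from = np.concatenate([np.cumsum(sorted_labels[::-1])[::-1], [0]])
    cum_neg_from = np.concatenate([np.cumsum((1 - sorted_labels)[::-1])[::-1], [0]])
    idx = np.searchsorted(sorted_scores, thresholds, side="left")
    tp = cum_pos_from[idx]
    fp = cum_neg_from[idx]
    odds = thresholds / (1.0 - thresholds)
    nb = tp / n - fp / n * odds
    nb_all = pi - (1.0 - pi) * odds
    return DecisionCurve(thresholds=thresholds, nb_model=nb,
                         nb_treat_all=nb_all,
                         nb_treat_none=np.zeros_like(thresholds))


# -- hyperparameter importance --------------------------------------------

def _exact_shapley(predict, X: np.ndarray, background: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact interventional Shapley values by coalition enumeration.

    ``predict`` maps an (n, d) array to predictions.  Returns
    ``(phi, base)`` with ``phi`` of shape (n, d); additivity
    ``base + phi.sum(1) == predict(X)`` holds to float precision.
    """
    from math import factorial

    n, d = X.shape
    if d > 12:
        raise ValueError("exact Shapley enumeration is limited to 12 features")
    B = background.shape[0]
    n_sub = 1 << d
    # value of every coalition for every explained row
    v = np.empty((n_sub, n))
    for s in range(n_sub):
        mixed = np.repeat(background[None, :, :], n, axis=0)  # (n, B, d)
        for j in range(d):
            if s >> j & 1:
                mixed[:, :, j] = X[:, j][:, None]
        v[s] = predict(mixed.reshape(n * B, d)).reshape(n, B).mean(axis=1)
    fact = [factorial(i) for i in range(d + 1)]
    phi = np.zeros((n, d))
    for s in range(n_sub):
        size = bin(s).count("1")
        for j in range(d):
            if s >> j & 1:
                continue
            w = fact[size] * fact[d - size - 1] / fact[d]
            phi[:, j] += w * (v[s | (1 << j)] - v[s])
    return phi, float(v[0].mean()) if n else 0.0


def hyperparam_importance(trials: pd.DataFrame, target: str = "val_auc",
                          n_trees: int = 200, seed: int = 0) -> dict:
    """Rank hyperparameters by mean |Shapley attribution| of a random-forest
    surrogate mapping hyperparameter settings to validation AUC.

    Returns ``{"summary": DataFrame, "attributions": DataFrame,
    "base_value": float}``; per-trial attributions plus base equal the
    forest prediction (Shapley efficiency), and the long-format
    ``attributions`` table is ready for a beeswarm-style plot.
    """
    from sklearn.ensemble import RandomForestRegressor

    if len(trials) < 10:
        raise ValueError("need at least 10 trials for hyperparameter importance")
    feats = [c for c in trials.columns if c != target]
    X = trials[feats].to_numpy(dtype=float)
    y = trials[target].to_numpy(dtype=float)
    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed)
    rf.fit(X, y)
    phi, base = _exact_shapley(rf.predict, X, X)
    summary = (pd.DataFrame({"hyperparameter": feats,
                             "mean_abs_attribution": np.abs(phi).mean(axis=0)})
               .sort_values("mean_abs_attribution", ascending=False)
               .reset_index(drop=True))
    long = pd.DataFrame({
        "trial": np.repeat(np.arange(len(X)), len(feats)),
        "hyperparameter": np.tile(feats, len(X)),
        "value": X.ravel(),
        "attribution": phi.ravel(),
    })
    return {"summary": summary, "attributions": long, "base_value": base}


# -- orchestration ---------------------------------------------------------

def evaluate_model(val_pred: Predictions, test_pred: Predictions,
                   thresholds: np.ndarray | None = None) -> dict:
    """Recalibrate on validation, then evaluate on test."""
    params = platt_fit(val_pred)
    recal = Predictions(platt_apply(test_pred.scores, params), test_pred.labels, "test")
    return {
        "recalibration": {"slope": params.slope, "intercept": params.intercept},
        "auc": auc_ci(recal),
        "auprc": auprc_ci(recal),
        "calibration": smooth_calibration(recal),
        "decision_curve": net_benefit(recal, thresholds),
        "predictions": recal,
    }


def evaluate_all(model_predictions: dict, thresholds: np.ndarray | None = None) -> dict:
    """``model_predictions``: name -> (val Predictions, test Predictions).

    Returns a report bundle: one entry per model with recalibration
    parameters, AUC/AUPRC with CIs, calibration curve and decision curve.
    """
    report = {}
    for name, (val_pred, test_pred) in model_predictions.items():
        report[name] = evaluate_model(val_pred, test_pred, thresholds)
    return report


def report_to_frame(report: dict) -> pd.DataFrame:
    rows = []
    for name, r in report.items():
        rows.append({
            "model": name,
            "auc": r["auc"].estimate, "auc_lo": r["auc"].lower, "auc_hi": r["auc"].upper,
            "auprc": r["auprc"].estimate, "auprc_lo": r["auprc"].lower,
            "auprc_hi": r["auprc"].upper,
            "recal_slope": r["recalibration"]["slope"],
            "recal_intercept": r["recalibration"]["intercept"],
        })
    return pd.DataFrame(rows)
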