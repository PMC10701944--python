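"""End-to-end study orchestration: split, featurize, fit, evaluate.

The flow mirrors a standard patient-level prediction protocol:

1. persons are randomized 75/25 to development/test, with a 67/33
   train/validation split inside development (no person straddles folds);
2. events are windowed into the static (365/180/30-day) matrix and the
   visit-sequence view; rare features (< 0.1% of observations) are
   dropped; age is max-abs scaled on training rows;
3. the linear (L1 logistic) and boosted-tree baselines are fit with
   3-fold CV on the development fold; the attention models train on the
   train fold with early stopping on validation; the distilled
   transformer uses the linear model as teacher;
4. every model is Platt-recalibrated on validation and evaluated on test
   (AUC/AUPRC with CIs, calibration curve, decision curve).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logit as _logit

from . import features as F
from .baselines import GradientBoostedTrees, LassoLogistic, select_top_features
from .estimators import RetainClassifier, SardClassifier, TransformerClassifier
from .metrics import Predictions, evaluate_all, report_to_frame

logger = logging.getLogger(__name__)

ALL_MODELS = ("lasso", "gbt", "retain", "transformer", "sard")


@dataclass
class RunConfig:
    windows: tuple = F.DEFAULT_WINDOWS
    min_prevalence: float = 0.001
    max_visits: int = 50
    include_index_date: bool = True
    test_frac: float = 0.25
    val_frac_of_train: float = 0.33
    seed: int = 0
    models: tuple = ALL_MODELS
    model_params: dict = field(default_factory=dict)  # name -> kwargs
    thresholds: np.ndarray | None = None
    reduced_k: int | None = None  # restrict to top-k LASSO features

    def params_for(self, name: str) -> dict:
        return dict(self.model_params.get(name, {}))


@dataclass
class StudyData:
    """Featurized, split study inputs shared by all models."""

    fm: F.FeatureMatrix
    sequences: list
    vocab: F.ConceptVocab
    labels: np.ndarray
    person_ids: np.ndarray
    split: F.SplitSpec
    masks: dict  # fold -> boolean row mask


def prepare_study(events, cohort, config: RunConfig) -> StudyData:
    labels = cohort["outcome"].to_numpy().astype(int)
    split = F.split_data(cohort, config.test_frac, config.val_frac_of_train,
                         config.seed)
    obs = np.arange(len(cohort))
    masks = {fold: split.mask(obs, fold) for fold in ("train", "validation", "test")}
    dev_mask = masks["train"] | masks["validation"]

    # age scaling fit on training rows only
    age_max = float(cohort.loc[masks["train"], "age_years"].abs().max())
    vocab = F.concept_vocab_from_events(events, cohort, max(config.windows),
                                        config.include_index_date)
    fm, _ = F.binarize_windows(events, cohort, config.windows, vocab=vocab,
                               include_index_date=config.include_index_date,
                               age_max=age_max)
    fm = F.filter_rare_features(fm, config.min_prevalence)
    kept_concepts = sorted({c for c, w in fm.feature_map.entries
                            if w == max(config.windows)})
    seq_vocab = F.ConceptVocab(kept_concepts)
    sequences, _, _ = F.build_sequences(events, cohort, max(config.windows),
                                        vocab=seq_vocab,
                                        max_visits=config.max_visits,
                                        include_index_date=config.include_index_date,
                                        age_max=age_max)
    return StudyData(fm=fm, sequences=sequences, vocab=seq_vocab, labels=labels,
                     person_ids=cohort["person_id"].to_numpy(), split=split,
                     masks={"train": masks["train"],
                            "validation": masks["validation"],
                            "test": masks["test"], "dev": dev_mask})


def _reduce_features(data: StudyData, lasso: LassoLogistic, k: int) -> StudyData:
    """Restrict the study to the top-k features by |LASSO coefficient|.

    Static columns ride along; the sequence vocabulary keeps concepts that
    appear in any retained window column.
    """
    idx, sub_map = select_top_features(lasso, k, data.fm.feature_map)
    static_idx = [i for i in data.fm.feature_map.static_indices() if i not in idx]
    keep = sorted(set(idx) | set(static_idx))
    fm = F.FeatureMatrix(data.fm.X[:, keep].tocsr(), data.fm.feature_map.subset(keep),
                         data.fm.obs_ids.copy())
    kept_concepts = sorted({c for c, w in fm.feature_map.entries if w != "static"})
    seq_vocab = F.ConceptVocab(kept_concepts)
    old_to_new = {}
    for ci, c in enumerate(data.vocab.concepts):
        if c in seq_vocab.index:
            old_to_new[ci] = seq_vocab.index[c]
    sequences = []
    for s in data.sequences:
        visits = []
        for d, cs in s.visits:
            mapped = tuple(sorted(old_to_new[c] for c in cs if c in old_to_new))
            if mapped:
                visits.append((d, mapped))
        sequences.append(F.VisitSequence(s.observation_id, visits, s.static.copy()))
    return StudyData(fm=fm, sequences=sequences, vocab=seq_vocab,
                     labels=data.labels, person_ids=data.person_ids,
                     split=data.split, masks=data.masks)


def fit_models(data: StudyData, config: RunConfig) -> dict:
    """Fit the requested roster; returns name -> fitted estimator."""
    m = data.masks
    y = data.labels
    fitted: dict = {}
    X = data.fm.X

    lasso = None
    if {"lasso", "sard"} & set(config.models) or config.reduced_k:
        lasso = LassoLogistic(random_state=config.seed,
                              **config.params_for("lasso"))
        lasso.fit(X[m["dev"]], y[m["dev"]])
        fitted["lasso"] = lasso

    if config.reduced_k:
        data = _reduce_features(data, lasso, config.reduced_k)
        X = data.fm.X
        lasso_r = LassoLogistic(random_state=config.seed,
                                **config.params_for("lasso"))
        lasso_r.fit(X[m["dev"]], y[m["dev"]])
        fitted["lasso"] = lasso_r
        lasso = lasso_r

    if "gbt" in config.models:
        gbt = GradientBoostedTrees(random_state=config.seed,
                                   **config.params_for("gbt"))
        gbt.fit(X[m["dev"]], y[m["dev"]])
        fitted["gbt"] = gbt

    seqs = data.sequences
    tr_idx = np.flatnonzero(m["train"])
    va_idx = np.flatnonzero(m["validation"])
    seq_tr = [seqs[i] for i in tr_idx]
    seq_va = [seqs[i] for i in va_idx]

    if "retain" in config.models:
        retain = RetainClassifier(n_concepts=len(data.vocab),
                                  max_visits=config.max_visits,
                                  random_state=config.seed,
                                  **config.params_for("retain"))
        retain.fit(seq_tr, y[tr_idx], X_val=seq_va, y_val=y[va_idx])
        fitted["retain"] = retain

    if "transformer" in config.models:
        trans = TransformerClassifier(n_concepts=len(data.vocab),
                                      max_visits=config.max_visits,
                                      random_state=config.seed,
                                      **config.params_for("transformer"))
        trans.fit(seq_tr, y[tr_idx], X_val=seq_va, y_val=y[va_idx])
        fitted["transformer"] = trans

    if "sard" in config.models:
        if lasso is None:
            raise ValueError("SARD requires the linear teacher")
        p_tr = np.clip(lasso.predict_proba(X[m["train"]])[:, 1], 1e-7, 1 - 1e-7)
        p_va = np.clip(lasso.predict_proba(X[m["validation"]])[:, 1], 1e-7, 1 - 1e-7)
        sard = SardClassifier(n_concepts=len(data.vocab),
                              max_visits=config.max_visits,
                              random_state=config.seed,
                              **config.params_for("sard"))
        sard.fit(seq_tr, y[tr_idx], teacher_logits=_logit(p_tr),
                 X_val=seq_va, y_val=y[va_idx], teacher_logits_val=_logit(p_va))
        fitted["sard"] = sard

    fitted["_data"] = data  # reduced view if reduced_k was set
    return fitted


def predict_fold(model, data: StudyData, fold: str) -> np.ndarray:
    idx = np.flatnonzero(data.masks[fold])
    if isinstance(model, (LassoLogistic, GradientBoostedTrees)):
        return model.predict_proba(data.fm.X[idx])[:, 1]
    return model.predict_proba([data.sequences[i] for i in idx])[:, 1]


def run_study(events, cohort, config: RunConfig) -> dict:
    """Full pipeline; returns the fitted models, predictions and report."""
    data = prepare_study(events, cohort, config)
    fitted = fit_models(data, config)
    data = fitted.pop("_data")
    preds = {}
    for name, model in fitted.items():
        val = Predictions(predict_fold(model, data, "validation"),
                          data.labels[data.masks["validation"]], "validation")
        test = Predictions(predict_fold(model, data, "test"),
                           data.labels[data.masks["test"]], "test")
        preds[name] = (val, test)
    report = evaluate_all(preds, config.thresholds)
    return {"data": data, "models": fitted, "predictions": preds,
            "report": report, "summary": report_to_frame(report)}
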