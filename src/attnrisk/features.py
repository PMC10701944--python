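"""Featurization of longitudinal coded health records.

Two views of the same records are produced, anchored at each observation's
index date with a 1-year lookback window:

* a **temporal view** (:class:`VisitSequence`): ordered visits, one per
  calendar date, each a set of concept indices with its day-offset before
  the index date — the input to the attention models; and
* a **static view** (:class:`FeatureMatrix`): a sparse binary matrix with
  one column per (concept, window) pair for lookback windows of 365, 180
  and 30 days, plus scaled age and sex — the input to the linear and
  boosted-tree baselines.

Both views share the window convention: an event is in window ``w`` iff
``0 <= index_date - event_date <= w`` (both endpoints inclusive; events on
the index date count, controllable via ``include_index_date``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

DEFAULT_WINDOWS = (365, 180, 30)
STATIC_AGE = ("age", "static")
STATIC_SEX = ("sex", "static")


class ConceptVocab:
    """Ordered concept-id vocabulary with bidirectional lookup."""

    def __init__(self, concept_ids):
        self.concepts = list(concept_ids)
        self.index = {c: i for i, c in enumerate(self.concepts)}
        if len(self.index) != len(self.concepts):
            raise ValueError("duplicate concept ids in vocabulary")

    def __len__(self):
        return len(self.concepts)

    def __contains__(self, c):
        return c in self.index

    def __eq__(self, other):
        return isinstance(other, ConceptVocab) and self.concepts == other.concepts


class FeatureMap:
    """Ordered (concept_id, window) column map; windows are day counts or
    ``"static"`` for demographic columns.  Indices are contiguous from 0 and
    (concept, window) pairs unique."""

    def __init__(self, entries):
        self.entries = [tuple(e) for e in entries]
        self.index = {e: i for i, e in enumerate(self.entries)}
        if len(self.index) != len(self.entries):
            raise ValueError("duplicate (concept, window) entries")

    def __len__(self):
        return len(self.entries)

    def __getitem__(self, i):
        return self.entries[i]

    def index_of(self, concept, window):
        return self.index[(concept, window)]

    def subset(self, indices) -> "FeatureMap":
        return FeatureMap([self.entries[i] for i in indices])

    def static_indices(self) -> list:
        return [i for i, (_, w) in enumerate(self.entries) if w == "static"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["concept_id", "window"])


@dataclass
class VisitSequence:
    """One observation's temporal record: visits oldest-first, each a
    (days_before_index, concept index set) pair, plus static covariates."""

    observation_id: int
    visits: list  # [(days_before_index, tuple_of_concept_indices), ...]
    static: np.ndarray  # [scaled_age, sex_indicator]

    def __post_init__(self):
        days = [d for d, _ in self.visits]
        if any(days[i] < days[i + 1] for i in range(len(days) - 1)):
            raise ValueError("visits must be ordered ascending in time "
                             "(descending days_before_index)")


@dataclass
class FeatureMatrix:
    """Sparse observation x feature matrix with its column map."""

    X: sp.csr_matrix
    feature_map: FeatureMap
    obs_ids: np.ndarray
    removal_log_: list = field(default_factory=list)

    @property
    def density(self) -> float:
        r, c = self.X.shape
        return self.X.nnz / (r * c) if r and c else 0.0

    @property
    def shape(self):
        return self.X.shape

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.X.copy(), FeatureMap(self.feature_map.entries),
                             self.obs_ids.copy())


@dataclass
class SplitSpec:
    """Observation -> fold assignment, grouped so that no person straddles
    folds."""

    assignment: dict  # observation_id -> "train" | "validation" | "test"
    seed: int

    def ids(self, fold: str) -> np.ndarray:
        return np.array([o for o, f in self.assignment.items() if f == fold])

    def mask(self, obs_ids: np.ndarray, fold: str) -> np.ndarray:
        return np.array([self.assignment[o] == fold for o in obs_ids])


# ---------------------------------------------------------------------------

def _events_with_offsets(events: pd.DataFrame, cohort: pd.DataFrame,
                         obs_window_days: int,
                         include_index_date: bool = True) -> pd.DataFrame:
    """Join events to cohort rows and compute days_before_index, keeping
    events inside the observation window."""
    coh = cohort.reset_index(drop=True).copy()
    coh["observation_id"] = np.arange(len(coh))
    merged = events.merge(
        coh[["observation_id", "person_id", "index_date"]], on="person_id", how="inner")
    days = (merged["index_date"] - merged["event_date"]).dt.days
    merged["days_before_index"] = days
    lo = 0 if include_index_date else 1
    keep = (days >= lo) & (days <= obs_window_days)
    return merged.loc[keep, ["observation_id", "concept_id", "days_before_index"]]


def concept_vocab_from_events(events: pd.DataFrame, cohort: pd.DataFrame,
                              obs_window_days: int = 365,
                              include_index_date: bool = True) -> ConceptVocab:
    inwin = _events_with_offsets(events, cohort, obs_window_days, include_index_date)
    return ConceptVocab(sorted(inwin["concept_id"].unique()))


def scaled_age(age_years: np.ndarray, max_age: float | None = None):
    """Max-abs scale ages; returns (scaled, max_used)."""
    age = np.asarray(age_years, dtype=float)
    m = float(np.max(np.abs(age))) if max_age is None else float(max_age)
    if m == 0:
        logger.warning("all-zero age column left unchanged by scaling")
        return age, 0.0
    return age / m, m


def build_sequences(events: pd.DataFrame, cohort: pd.DataFrame,
                    obs_window_days: int = 365,
                    vocab: ConceptVocab | None = None,
                    max_visits: int = 50,
                    include_index_date: bool = True,
                    age_max: float | None = None):
    """Group each observation's in-window events into per-calendar-date
    visits of deduplicated concept indices.

    Returns ``(sequences, vocab, age_max)``.  Observations with no
    qualifying events get an empty visit list (statics only).  When the
    visit count exceeds ``max_visits`` the *oldest* visits are dropped.
    """
    if obs_window_days < 0:
        raise ValueError("obs_window_days must be non-negative")
    inwin = _events_with_offsets(events, cohort, obs_window_days, include_index_date)
    if vocab is None:
        vocab = ConceptVocab(sorted(inwin["concept_id"].unique()))
    inwin = inwin[inwin["concept_id"].isin(vocab.index)]
    cidx = inwin["concept_id"].map(vocab.index)

    coh = cohort.reset_index(drop=True)
    age_s, age_max = scaled_age(coh["age_years"].to_numpy(), age_max)
    sex_ind = (coh["sex"].astype(str).str.lower() == "male").astype(float).to_numpy()

    grouped: dict[int, dict[int, set]] = {}
    for obs, day, ci in zip(inwin["observation_id"].to_numpy(),
                            inwin["days_before_index"].to_numpy(),
                            cidx.to_numpy()):
        grouped.setdefault(obs, {}).setdefault(int(day), set()).add(int(ci))

    sequences = []
    for obs in range(len(coh)):
        visits = []
        if obs in grouped:
            # oldest first = descending days_before_index
            for day in sorted(grouped[obs], reverse=True):
                visits.append((day, tuple(sorted(grouped[obs][day]))))
        if len(visits) > max_visits:
            visits = visits[-max_visits:]  # keep most recent
        sequences.append(VisitSequence(
            observation_id=obs, visits=visits,
            static=np.array([age_s[obs], sex_ind[obs]])))
    return sequences, vocab, age_max


def binarize_windows(events: pd.DataFrame, cohort: pd.DataFrame,
                     windows=DEFAULT_WINDOWS,
                     vocab: ConceptVocab | None = None,
                     include_index_date: bool = True,
                     age_max: float | None = None):
    """Sparse binary (concept, window) matrix plus static age/sex columns.

    Column (c, w) is 1 iff concept c occurs in [index - w, index] for the
    observation.  Returns ``(FeatureMatrix, age_max)``; age is max-abs
    scaled with ``age_max`` (fit here if not supplied — refit on training
    rows via :func:`scale_numeric` to avoid leakage in a real split).
    """
    windows = list(windows)
    if len(set(windows)) != len(windows) or any(w <= 0 for w in windows):
        raise ValueError("windows must be positive and distinct")
    wmax = max(windows)
    inwin = _events_with_offsets(events, cohort, wmax, include_index_date)
    if vocab is None:
        vocab = ConceptVocab(sorted(inwin["concept_id"].unique()))
    inwin = inwin[inwin["concept_id"].isin(vocab.index)]
    cidx = inwin["concept_id"].map(vocab.index).to_numpy()
    obs = inwin["observation_id"].to_numpy()
    days = inwin["days_before_index"].to_numpy()

    n_rows = len(cohort)
    n_c = len(vocab)
    entries = [(c, w) for w in windows for c in vocab.concepts]
    entries += [STATIC_AGE, STATIC_SEX]
    fmap = FeatureMap(entries)

    blocks = []
    for wi, w in enumerate(windows):
        m = days <= w
        pairs = np.unique(np.stack([obs[m], cidx[m]], axis=1), axis=0) if m.any() \
            else np.empty((0, 2), dtype=int)
        block = sp.csr_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n_rows, n_c))
        blocks.append(block)

    coh = cohort.reset_index(drop=True)
    age_s, age_max = scaled_age(coh["age_years"].to_numpy(), age_max)
    sex_ind = (coh["sex"].astype(str).str.lower() == "male").astype(float).to_numpy()
    statics = sp.csr_matrix(np.stack([age_s, sex_ind], axis=1))
    X = sp.hstack(blocks + [statics], format="csr")
    return FeatureMatrix(X, fmap, np.arange(n_rows)), age_max


def filter_rare_features(fm: FeatureMatrix, min_prevalence: float = 0.001) -> FeatureMatrix:
    """Drop columns present in fewer than ``min_prevalence`` of rows
    (strictly-less-than removal); static columns are always retained."""
    if not (0.0 <= min_prevalence <= 1.0):
        raise ValueError("min_prevalence must be in [0, 1]")
    n_rows = fm.X.shape[0]
    if n_rows == 0:
        raise ValueError("empty feature matrix")
    counts = np.asarray((fm.X != 0).sum(axis=0)).ravel()
    static = set(fm.feature_map.static_indices())
    keep = [i for i in range(fm.X.shape[1])
            if i in static or counts[i] / n_rows >= min_prevalence]
    removed = [fm.feature_map[i] for i in range(fm.X.shape[1]) if i not in set(keep)]
    for entry in removed:
        logger.info("filter_rare_features: removed %s", entry)
    out = FeatureMatrix(fm.X[:, keep].tocsr(), fm.feature_map.subset(keep),
                        fm.obs_ids.copy())
    out.removal_log_ = removed
    return out


def scale_numeric(fm: FeatureMatrix, train_mask: np.ndarray | None = None):
    """Max-abs scale numeric (non-binary) columns using training rows only.

    Returns ``(scaled FeatureMatrix, params)`` where ``params`` maps column
    index -> divisor, reusable on held-out rows (which may then exceed 1).
    All-zero numeric columns are left unchanged with a warning.
    """
    X = fm.X.tocsc()
    n = X.shape[0]
    if train_mask is None:
        train_mask = np.ones(n, dtype=bool)
    params = {}
    for j in range(X.shape[1]):
        col = X[:, j].toarray().ravel()
        vals = np.unique(col)
        if np.all(np.isin(vals, (0.0, 1.0))):
            continue  # binary column untouched
        m = float(np.max(np.abs(col[train_mask])))
        if m == 0.0:
            logger.warning("scale_numeric: all-zero numeric column %d left unchanged", j)
            continue
        params[j] = m
    return apply_scaling(fm, params), params


def apply_scaling(fm: FeatureMatrix, params: dict) -> FeatureMatrix:
    d = np.ones(fm.X.shape[1])
    for j, m in params.items():
        d[j] = 1.0 / m
    Xs = (fm.X.astype(float) @ sp.diags(d)).tocsr()
    return FeatureMatrix(Xs, FeatureMap(fm.feature_map.entries), fm.obs_ids.copy())


def split_data(cohort: pd.DataFrame, test_frac: float = 0.25,
               val_frac_of_train: float = 0.33, seed: int = 0) -> SplitSpec:
    """Randomize *persons* to train/validation/test; every observation of a
    person lands in the same fold.  Deterministic under ``seed``."""
    for f in (test_frac, val_frac_of_train):
        if not (0.0 < f < 1.0):
            raise ValueError("fractions must lie in (0, 1)")
    coh = cohort.reset_index(drop=True)
    persons = coh["person_id"].unique()
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(persons))
    persons = persons[perm]
    n = len(persons)
    n_test = int(round(n * test_frac))
    n_val = int(round((n - n_test) * val_frac_of_train))
    fold_of = {}
    for p in persons[:n_test]:
        fold_of[p] = "test"
    for p in persons[n_test:n_test + n_val]:
        fold_of[p] = "validation"
    for p in persons[n_test + n_val:]:
        fold_of[p] = "train"
    assignment = {int(i): fold_of[p] for i, p in enumerate(coh["person_id"])}
    return SplitSpec(assignment=assignment, seed=seed)
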