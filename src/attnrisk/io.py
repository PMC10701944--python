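"""Flat-file readers and writers for event-level records and cohorts.

Events and cohorts are delimited text (CSV or TSV, autodetected from the
header line or set explicitly).  Dates are ISO-8601 in files and held as
``datetime64`` in memory.  Concept ids are opaque strings; no vocabulary
mapping is attempted.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

EVENT_COLUMNS = ("person_id", "concept_id", "event_date", "domain")
COHORT_COLUMNS = ("person_id", "index_date", "outcome", "age_years", "sex")


class SchemaError(ValueError):
    """A required column is missing or a value violates the schema."""


class RowError(ValueError):
    """A row-level parse failure, annotated with the offending line."""


def _detect_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    header = Path(path).open().readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def _read_table(path, required, sep=None, column_map=None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_detect_sep(path, sep), dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return df


def _parse_dates(series: pd.Series, colname: str) -> pd.Series:
    parsed = pd.to_datetime(series, format="ISO8601", errors="coerce")
    bad = parsed.isna() & series.astype(str).str.len().gt(0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        # +2: header line plus 1-based numbering
        raise RowError(f"unparseable {colname} {series.iloc[row]!r} at line {row + 2}")
    if parsed.isna().any():
        row = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise RowError(f"empty {colname} at line {row + 2}")
    return parsed


def read_events(path, sep: str | None = None, column_map: dict | None = None) -> pd.DataFrame:
    """Read event-level records: person_id, concept_id, event_date, domain.

    Row order is preserved; dates are normalized to ``datetime64``.
    Raises :class:`SchemaError` for missing columns and :class:`RowError`
    (with the line number) for unparseable dates.
    """
    df = _read_table(path, EVENT_COLUMNS, sep, column_map)
    if len(df) == 0:
        return pd.DataFrame({c: pd.Series(dtype="datetime64[ns]" if c == "event_date"
                                          else "object") for c in EVENT_COLUMNS})
    empty = df["concept_id"].astype(str).str.len() == 0
    if empty.any():
        row = int(np.flatnonzero(empty.to_numpy())[0])
        raise RowError(f"empty concept_id at line {row + 2}")
    df = df[list(EVENT_COLUMNS)].copy()
    df["event_date"] = _parse_dates(df["event_date"], "event_date")
    return df


def read_cohort(path, sep: str | None = None, column_map: dict | None = None,
                allow_duplicates: bool = False) -> pd.DataFrame:
    """Read the cohort table: person_id, index_date, outcome, age_years, sex.

    Outcomes are coerced to {0,1}; anything else raises.  Duplicate
    (person_id, index_date) rows raise unless ``allow_duplicates`` (a
    person can legitimately have several index visits, but identical rows
    usually indicate an extraction bug).
    """
    df = _read_table(path, COHORT_COLUMNS, sep, column_map)
    if len(df) == 0:
        out = pd.DataFrame(columns=list(COHORT_COLUMNS))
        return out
    df = df[list(COHORT_COLUMNS)].copy()
    df["index_date"] = _parse_dates(df["index_date"], "index_date")
    out_raw = df["outcome"].astype(str).str.strip()
    ok = out_raw.isin(["0", "1", "0.0", "1.0", "True", "False", "true", "false"])
    if not ok.all():
        row = int(np.flatnonzero((~ok).to_numpy())[0])
        raise SchemaError(f"outcome {out_raw.iloc[row]!r} at line {row + 2} "
                          "is not binary")
    df["outcome"] = out_raw.isin(["1", "1.0", "True", "true"]).astype(int)
    df["age_years"] = pd.to_numeric(df["age_years"], errors="raise").astype(float)
    if (df["age_years"] < 0).any():
        raise SchemaError("negative age_years")
    sex = df["sex"].astype(str).str.lower()
    if not sex.isin(["female", "male", "f", "m"]).all():
        raise SchemaError("sex must be female/male")
    df["sex"] = sex.map({"f": "female", "m": "male"}).fillna(sex)
    if not allow_duplicates:
        dup = df.duplicated(subset=["person_id", "index_date"])
        if dup.any():
            raise SchemaError("duplicate (person_id, index_date) rows; pass "
                              "allow_duplicates=True to keep them")
    return df


def cohort_summary(cohort: pd.DataFrame) -> dict:
    n = len(cohort)
    return {
        "observations": n,
        "outcomes": int(cohort["outcome"].sum()) if n else 0,
        "prevalence": float(cohort["outcome"].mean()) if n else float("nan"),
        "n_persons": int(cohort["person_id"].nunique()) if n else 0,
    }


# -- matrix / sequence serialization ---------------------------------------

def write_feature_matrix(fm, outdir, prefix: str = "features") -> None:
    """MatrixMarket matrix plus sidecar feature-map and row-id TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / f"{prefix}.mtx"), fm.X)
    fm.feature_map.to_frame().to_csv(outdir / f"{prefix}.columns.tsv", sep="\t", index=False)
    pd.DataFrame({"observation_id": fm.obs_ids}).to_csv(
        outdir / f"{prefix}.rows.tsv", sep="\t", index=False)


def read_feature_matrix(outdir, prefix: str = "features"):
    from .features import FeatureMap, FeatureMatrix

    outdir = Path(outdir)
    X = sp.csr_matrix(mmread(str(outdir / f"{prefix}.mtx")))
    cols = pd.read_csv(outdir / f"{prefix}.columns.tsv", sep="\t")
    entries = []
    for _, row in cols.iterrows():
        w = row["window"]
        entries.append((row["concept_id"], w if w == "static" else int(w)))
    rows = pd.read_csv(outdir / f"{prefix}.rows.tsv", sep="\t")
    return FeatureMatrix(X, FeatureMap(entries), rows["observation_id"].to_numpy())


def write_sequences(sequences, vocab, path) -> None:
    """JSON-lines: one record per observation with visits and statics."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(json.dumps({"vocab": list(vocab.concepts)}) + "\n")
        for seq in sequences:
            rec = {
                "observation_id": int(seq.observation_id),
                "visits": [[int(d), list(map(int, cs))] for d, cs in seq.visits],
                "static": [float(v) for v in seq.static],
            }
            fh.write(json.dumps(rec) + "\n")


def read_sequences(path):
    from .features import ConceptVocab, VisitSequence

    path = Path(path)
    sequences = []
    vocab = None
    with path.open() as fh:
        header = json.loads(fh.readline())
        vocab = ConceptVocab(header["vocab"])
        for line in fh:
            rec = json.loads(line)
            sequences.append(VisitSequence(
                observation_id=rec["observation_id"],
                visits=[(d, tuple(cs)) for d, cs in rec["visits"]],
                static=np.array(rec["static"], dtype=float)))
    return sequences, vocab
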