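import numpy as np
import pandas as pd
import pytest

from attnrisk.simulate import SimConfig, generate, planted_beta


def write_csv(path, text):
    path.write_text(text.strip() + "\n")
    return path


@pytest.fixture()
def events_file(tmp_path):
    return write_csv(tmp_path / "events.csv", """
person_id,concept_id,event_date,domain
p1,C1,2020-01-10,condition
p1,C2,2020-02-01,drug
p2,C1,2019-12-25,procedure
""")


@pytest.fixture()
def cohort_file(tmp_path):
    return write_csv(tmp_path / "cohort.csv", """
person_id,index_date,outcome,age_years,sex
p1,2020-02-15,0,63.5,female
p2,2020-01-30,1,71.0,male
p3,2020-03-01,1,58.0,female
""")


def make_events(rows):
    df = pd.DataFrame(rows, columns=["person_id", "concept_id", "event_date", "domain"])
    df["event_date"] = pd.to_datetime(df["event_date"])
    return df


def make_cohort(rows):
    df = pd.DataFrame(rows, columns=["person_id", "index_date", "outcome",
                                     "age_years", "sex"])
    df["index_date"] = pd.to_datetime(df["index_date"])
    return df


@pytest.fixture(scope="session")
def small_sim():
    """A modest synthetic cohort with planted effects, shared across tests."""
    cfg = SimConfig(n_persons=2000, n_concepts=120,
                    beta=planted_beta(120, {10: 2.0, 18: -1.5, 27: 1.2}),
                    outcome_prevalence_target=0.08, recency_boost=1.0, seed=7)
    events, cohort, truth = generate(cfg)
    return cfg, events, cohort, truth


@pytest.fixture(scope="session")
def memorization_batch():
    """64 observations with random tiny sequences, for overfit/distill checks."""
    from attnrisk.features import VisitSequence
    from attnrisk.models_attention import pack_sequences

    rng = np.random.default_rng(11)
    n_concepts = 20
    seqs = []
    for i in range(64):
        n_vis = rng.integers(1, 6)
        days = np.sort(rng.integers(0, 365, n_vis))[::-1]
        visits = [(int(d), tuple(sorted(rng.choice(n_concepts,
                                                   rng.integers(1, 4),
                                                   replace=False))))
                  for d in days]
        seqs.append(VisitSequence(i, visits,
                                  np.array([rng.uniform(0.4, 0.9),
                                            float(rng.integers(0, 2))])))
    labels = rng.integers(0, 2, 64)
    # ensure both classes
    labels[0], labels[1] = 0, 1
    batch = pack_sequences(seqs, n_concepts, max_visits=10)
    return seqs, batch, labels, n_concepts
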