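"""Architecture semantics: embeddings, time encoding, attention
normalization, masking equivalence with unbatched evaluation, symmetry."""

import numpy as np
import pytest

from attnrisk.autodiff import Tensor
from attnrisk.features import VisitSequence
from attnrisk.models_attention import (RetainConfig, RetainNet, TransformerConfig,
                                       TransformerNet, embed_visits,
                                       pack_sequences, retain_forward,
                                       sinusoidal_time_embedding,
                                       transformer_forward)


def _seq(obs, visits, static=(0.5, 1.0)):
    return VisitSequence(obs, visits, np.array(static))


# -- sinusoidal time embedding --------------------------------------------

def test_time_embedding_offset_zero():
    e = sinusoidal_time_embedding(np.array([0]), 8)
    np.testing.assert_allclose(e[0, 0::2], 0.0)
    np.testing.assert_allclose(e[0, 1::2], 1.0)


def test_time_embedding_closed_form():
    e = sinusoidal_time_embedding(np.array([1]), 4)
    f1 = 10000.0 ** (-2 / 4)
    np.testing.assert_allclose(
        e[0], [np.sin(1), np.cos(1), np.sin(f1), np.cos(f1)], atol=1e-12)


def test_time_embedding_range_and_odd_dim():
    e = sinusoidal_time_embedding(np.arange(0, 365, 7), 16)
    assert np.all((e >= -1) & (e <= 1))
    with pytest.raises(ValueError):
        sinusoidal_time_embedding(np.array([3]), 5)


# -- visit embedding -------------------------------------------------------

def test_embed_visits_sums_concept_rows():
    seqs = [_seq(0, [(10, (0,))]), _seq(1, [(10, (0, 2))])]
    batch = pack_sequences(seqs, n_concepts=3)
    rng = np.random.default_rng(0)
    table = Tensor(rng.normal(size=(4, 5)))  # 3 concepts + null token
    out = embed_visits(batch, table, include_static=False)
    np.testing.assert_allclose(out.data[0, 0], table.data[0], atol=1e-12)
    np.testing.assert_allclose(out.data[1, 0], table.data[0] + table.data[2],
                               atol=1e-12)
    zero = embed_visits(batch, Tensor(np.zeros((4, 5))), include_static=False)
    np.testing.assert_allclose(zero.data, 0.0)


def test_embed_visits_concatenates_statics_and_time():
    seqs = [_seq(0, [(73, (1,))], static=(0.61, 1.0))]
    batch = pack_sequences(seqs, n_concepts=3)
    table = Tensor(np.zeros((4, 2)))
    out = embed_visits(batch, table, include_static=True, include_time=True)
    np.testing.assert_allclose(out.data[0, 0], [0, 0, 0.61, 1.0, 73 / 365])


def test_embed_visits_rejects_out_of_vocab():
    seqs = [_seq(0, [(10, (9,))])]  # concept 9 outside a vocabulary of 8
    batch = pack_sequences(seqs, n_concepts=8)
    with pytest.raises(IndexError):
        embed_visits(batch, Tensor(np.zeros((9, 4))))


# -- RETAIN ----------------------------------------------------------------

def test_retain_single_visit_attention_is_one():
    net = RetainNet(5, RetainConfig(embedding_dim=4, lstm_hidden_dim=3), seed=0)
    batch = pack_sequences([_seq(0, [(20, (1, 2))])], 5)
    out = retain_forward(batch, net)
    np.testing.assert_allclose(out.visit_attention, [[1.0]], atol=1e-15)
    assert 0 < out.scores[0] < 1


def test_retain_identical_visits_equal_attention_with_tied_directions():
    """With direction-tied LSTM parameters and a direction-symmetric
    attention projection, two identical visits must get weight 1/2 each
    (time-reversal symmetry of the architecture).  Statics are excluded so
    the concatenated visit time does not break the visits' identity."""
    net = RetainNet(5, RetainConfig(embedding_dim=4, lstm_hidden_dim=3,
                                    include_static=False), seed=1)
    for lstm in (net.lstm_alpha, net.lstm_beta):
        for name in ("Wx", "Wh", "b"):
            getattr(lstm.bwd, name).data[...] = getattr(lstm.fwd, name).data
    H = 3
    net.alpha_proj.W.data[H:] = net.alpha_proj.W.data[:H]
    batch = pack_sequences([_seq(0, [(30, (1, 3)), (10, (1, 3))])], 5)
    out = retain_forward(batch, net)
    np.testing.assert_allclose(out.visit_attention[0], [0.5, 0.5], atol=1e-12)


def test_retain_attention_normalized_and_masked(small_sim):
    from attnrisk.features import build_sequences

    _, events, cohort, _ = small_sim
    seqs, vocab, _ = build_sequences(events, cohort.head(40))
    net = RetainNet(len(vocab), RetainConfig(embedding_dim=6, lstm_hidden_dim=4))
    batch = pack_sequences(seqs, len(vocab), max_visits=12)
    out = retain_forward(batch, net)
    np.testing.assert_allclose(out.visit_attention.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(out.visit_attention[~batch.visit_mask] == 0.0)


def test_retain_batched_equals_unbatched():
    rng = np.random.default_rng(2)
    seqs = []
    for i in range(6):
        n_vis = rng.integers(1, 5)
        days = sorted(rng.integers(0, 365, n_vis).tolist(), reverse=True)
        seqs.append(_seq(i, [(int(d), tuple(sorted(set(rng.integers(0, 9, 2)))))
                             for d in days],
                         static=(rng.uniform(0, 1), float(rng.integers(0, 2)))))
    net = RetainNet(9, RetainConfig(embedding_dim=5, lstm_hidden_dim=4), seed=3)
    batched = retain_forward(pack_sequences(seqs, 9), net).scores
    solo = np.array([retain_forward(pack_sequences([s], 9), net).scores[0]
                     for s in seqs])
    np.testing.assert_allclose(batched, solo, atol=1e-5)


def test_retain_empty_sequence_uses_statics():
    net = RetainNet(5, RetainConfig(embedding_dim=4, lstm_hidden_dim=3), seed=4)
    a = retain_forward(pack_sequences([_seq(0, [], static=(0.2, 0.0))], 5), net)
    b = retain_forward(pack_sequences([_seq(0, [], static=(0.9, 1.0))], 5), net)
    assert np.isfinite(a.scores[0]) and a.scores[0] != b.scores[0]


# -- transformer -----------------------------------------------------------

def _random_seqs(rng, n, n_concepts=9):
    seqs = []
    for i in range(n):
        n_vis = rng.integers(1, 5)
        days = sorted(rng.integers(0, 365, n_vis).tolist(), reverse=True)
        seqs.append(_seq(i, [(int(d), tuple(sorted(set(rng.integers(
            0, n_concepts, 2))))) for d in days],
            static=(rng.uniform(0, 1), float(rng.integers(0, 2)))))
    return seqs


def test_transformer_attention_rows_sum_to_one():
    rng = np.random.default_rng(5)
    seqs = _random_seqs(rng, 5)
    net = TransformerNet(9, TransformerConfig(embedding_dim=8, num_heads=2))
    batch = pack_sequences(seqs, 9)
    net.eval()
    net.forward(batch)
    w = net.blocks[-1].attn.last_weights
    np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-12)
    assert np.all(w >= 0)
    # padded keys receive exactly zero attention from every query
    key_pad = ~batch.visit_mask  # (B, T)
    for b in range(w.shape[0]):
        assert np.all(w[b][:, :, key_pad[b]] == 0.0)


def test_transformer_batched_equals_unbatched():
    rng = np.random.default_rng(6)
    seqs = _random_seqs(rng, 6)
    net = TransformerNet(9, TransformerConfig(embedding_dim=8, num_heads=2),
                         seed=7)
    batched = transformer_forward(pack_sequences(seqs, 9), net).scores
    solo = np.array([transformer_forward(pack_sequences([s], 9), net).scores[0]
                     for s in seqs])
    np.testing.assert_allclose(batched, solo, atol=1e-5)


def test_transformer_permutation_invariance_mean_head():
    """Permuting two visits together with their day offsets leaves the
    mean-pooled score unchanged (self-attention is permutation-equivariant
    and mean pooling symmetric)."""
    net = TransformerNet(6, TransformerConfig(embedding_dim=8, num_heads=2,
                                              head="mean"), seed=8)
    s1 = _seq(0, [(300, (1, 2)), (100, (3,)), (10, (0, 4))])
    s2 = _seq(0, [(300, (1, 2)), (100, (3,)), (10, (0, 4))])
    # permute two visits together with their offsets (bypass the sort check)
    s2.visits = [s1.visits[0], s1.visits[2], s1.visits[1]]
    a = transformer_forward(pack_sequences([s1], 6), net).scores[0]
    b = transformer_forward(pack_sequences([s2], 6), net).scores[0]
    assert a == pytest.approx(b, abs=1e-10)


def test_transformer_gradients_finite():
    rng = np.random.default_rng(9)
    seqs = _random_seqs(rng, 8)
    for net in (TransformerNet(9, TransformerConfig(embedding_dim=8,
                                                    num_heads=2), seed=10),
                RetainNet(9, RetainConfig(embedding_dim=5, lstm_hidden_dim=4),
                          seed=10)):
        batch = pack_sequences(seqs, 9)
        logits = net(batch)
        loss = (logits * logits).mean()
        loss.backward()
        for name, p in net.named_parameters():
            assert p.grad is None or np.all(np.isfinite(p.grad)), name


def test_transformer_config_validation():
    with pytest.raises(ValueError):
        TransformerConfig(embedding_dim=10, num_heads=3)
    with pytest.raises(ValueError):
        RetainConfig(embedding_dim=0)
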