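"""Encoder contracts: visit pooling, demographic token, attention masking,
causality, parameter accounting, and checkpoint integrity."""

import numpy as np
import pytest

from claimpt.data_model import PatientRecord, Visit
from claimpt.encoder import (
    ALL_CHANNELS,
    BIDIRECTIONAL,
    CAUSAL,
    ChannelFlags,
    Checkpoint,
    EncoderConfig,
    ModelParameters,
    bind_vocab,
    date_bucket,
    demographic_onehot,
    embed_visit,
    encode_patient,
    expected_parameter_count,
    transformer_layer,
)


def _visit(date, dx, vtype="OP"):
    return Visit(service_date=date, visit_type=vtype, codes={"DIAG": dx})


# -- visit embedding ---------------------------------------------------------


def test_visit_embedding_is_invariant_to_code_order(tiny_model, tiny_vocab):
    codes = ["D0003", "D0001", "D0010"]
    a = embed_visit(_visit(16000, codes), tiny_model, tiny_vocab)
    b = embed_visit(_visit(16000, list(reversed(codes))), tiny_model, tiny_vocab)
    assert np.array_equal(a, b)


def test_visit_embedding_is_elementwise_max_of_rows(tiny_model, tiny_vocab):
    tiny_model = tiny_model.copy()  # this test edits embedding rows
    codes_only = ChannelFlags(util=False, date=False)
    ia = tiny_vocab.global_index("DIAG", "D0001")
    ib = tiny_vocab.global_index("DIAG", "D0002")
    E = tiny_model.tensors["E_code"].data
    E[ia] = 0.0
    E[ia][0] = 1.0
    E[ib] = 0.0
    E[ib][1] = 1.0
    out = embed_visit(_visit(16000, ["D0001", "D0002"]), tiny_model, tiny_vocab, codes_only)
    expect = np.zeros(tiny_model.config.d, dtype=np.float32)
    expect[0] = expect[1] = 1.0
    assert np.array_equal(out, expect)


def test_single_code_visit_pools_code_type_and_date_rows(tiny_model, tiny_vocab):
    visit = _visit(16010, ["D0005"], vtype="IP")
    out = embed_visit(visit, tiny_model, tiny_vocab, prev_date=16000)
    r = tiny_model.tensors["E_code"].data[tiny_vocab.global_index("DIAG", "D0005")]
    u = tiny_model.tensors["E_type"].data[0]  # IP
    g = tiny_model.tensors["E_date"].data[date_bucket(10)]
    assert np.allclose(out, np.maximum(np.maximum(r, u), g))


def test_visit_with_no_contributing_rows_is_rejected(tiny_model, tiny_vocab):
    none_on = ChannelFlags(diag=False, proc=False, drug=False, util=False, date=False)
    with pytest.raises(ValueError):
        embed_visit(_visit(16000, ["D0001"]), tiny_model, tiny_vocab, none_on)


def test_date_buckets_partition_gap_range():
    assert [date_bucket(g) for g in (0, 1, 7, 8, 30, 31, 90, 91, 365, 366)] == [
        0, 1, 1, 2, 2, 3, 3, 4, 4, 5,
    ]


# -- demographic token -------------------------------------------------------


def test_demographic_onehot_buckets_ages_annually():
    assert np.array_equal(demographic_onehot("F", 10.4), demographic_onehot("F", 10.9))
    assert not np.array_equal(demographic_onehot("F", 10.4), demographic_onehot("F", 11.1))
    assert not np.array_equal(demographic_onehot("F", 10.4), demographic_onehot("M", 10.4))
    # ages beyond the pediatric range share the 19+ bucket
    assert np.array_equal(demographic_onehot("M", 19.0), demographic_onehot("M", 40.0))
    with pytest.raises(ValueError):
        demographic_onehot("M", -1.0)


def test_zero_projection_gives_zero_demographic_token(tiny_model, tiny_vocab):
    tiny_model = tiny_model.copy()
    tiny_model.tensors["W_demo"].data[:] = 0.0
    rec = PatientRecord("p", "F", 2004, [_visit(16000, ["D0001"])])
    from claimpt.encoder import encode_batch, prepare_batch

    batch = prepare_batch([rec], tiny_vocab, tiny_model.config)
    demo_tok = batch.demo @ tiny_model.tensors["W_demo"].data
    assert np.array_equal(demo_tok, np.zeros_like(demo_tok))


# -- transformer layer -------------------------------------------------------


def _numpy_transformer_oracle(x, params, layer, mask):
    """Independent float64 re-implementation with explicit per-head loops."""
    p = {k: v.data.astype(np.float64) for k, v in params.tensors.items()}
    cfg = params.config
    L, d = x.shape
    H, dh = cfg.n_heads, d // cfg.n_heads

    def ln(v, g, b):
        mu = v.mean(-1, keepdims=True)
        var = ((v - mu) ** 2).mean(-1, keepdims=True)
        return (v - mu) / np.sqrt(var + cfg.layernorm_eps) * g + b

    q = x @ p[f"L{layer}.Wq"] + p[f"L{layer}.bq"]
    k = x @ p[f"L{layer}.Wk"] + p[f"L{layer}.bk"]
    v = x @ p[f"L{layer}.Wv"] + p[f"L{layer}.bv"]
    ctx = np.zeros((L, d))
    for h in range(H):
        sl = slice(h * dh, (h + 1) * dh)
        scores = q[:, sl] @ k[:, sl].T / np.sqrt(dh)
        scores[~mask] = -1e9
        w = np.exp(scores - scores.max(-1, keepdims=True))
        w /= w.sum(-1, keepdims=True)
        ctx[:, sl] = w @ v[:, sl]
    h1 = ln(x + ctx @ p[f"L{layer}.Wo"] + p[f"L{layer}.bo"],
            p[f"L{layer}.ln1_g"], p[f"L{layer}.ln1_b"])
    ffn = np.maximum(h1 @ p[f"L{layer}.W1"] + p[f"L{layer}.b1"], 0) @ p[
        f"L{layer}.W2"
    ] + p[f"L{layer}.b2"]
    return ln(h1 + ffn, p[f"L{layer}.ln2_g"], p[f"L{layer}.ln2_b"])


def test_masked_layer_matches_independent_oracle(tiny_model):
    rng = np.random.default_rng(5)
    x = rng.normal(size=(5, tiny_model.config.d)).astype(np.float32)
    mask = np.tril(np.ones((5, 5), dtype=bool))
    out = transformer_layer(x, tiny_model, mask)
    oracle = _numpy_transformer_oracle(x.astype(np.float64), tiny_model, 0, mask)
    assert np.abs(out - oracle).max() < 1e-4


def test_attention_rows_sum_to_one_and_single_position_weight_is_one(tiny_model):
    rng = np.random.default_rng(6)
    x1 = rng.normal(size=(1, tiny_model.config.d)).astype(np.float32)
    _, attn = transformer_layer(x1, tiny_model, return_attn=True)
    assert np.allclose(attn, 1.0)
    x5 = rng.normal(size=(5, tiny_model.config.d)).astype(np.float32)
    mask = np.tril(np.ones((5, 5), dtype=bool))
    _, attn5 = transformer_layer(x5, tiny_model, mask, return_attn=True)
    assert np.allclose(attn5.sum(axis=-1), 1.0, atol=1e-6)
    assert np.allclose(attn5[:, 0, 1], 0.0)  # masked position gets zero weight


def test_all_forbidden_mask_row_rejected(tiny_model):
    x = np.zeros((2, tiny_model.config.d), dtype=np.float32)
    mask = np.array([[True, False], [False, False]])
    with pytest.raises(ValueError, match="mask"):
        transformer_layer(x, tiny_model, mask)


# -- patient encoding --------------------------------------------------------


def _two_visit_record(last_dx):
    return PatientRecord(
        "p", "M", 2003,
        [_visit(16000, ["D0001"]), _visit(16030, ["D0002"]), _visit(16060, last_dx)],
    )


def test_visit_state_count_matches_record(tiny_model):
    enc = encode_patient(_two_visit_record(["D0003"]), tiny_model)
    assert enc.visit_states.shape == (3, tiny_model.config.d)
    assert enc.pe.shape == (tiny_model.config.d,)


def test_causal_mode_is_blind_to_future_visits(tiny_model):
    a = encode_patient(_two_visit_record(["D0003"]), tiny_model, mode=CAUSAL)
    b = encode_patient(_two_visit_record(["D0009"]), tiny_model, mode=CAUSAL)
    assert np.array_equal(a.pe, b.pe)  # position 0 sees nothing later
    assert np.array_equal(a.visit_states[:2], b.visit_states[:2])
    assert not np.array_equal(a.visit_states[2], b.visit_states[2])


def test_bidirectional_mode_sees_the_whole_sequence(tiny_model):
    a = encode_patient(_two_visit_record(["D0003"]), tiny_model, mode=BIDIRECTIONAL)
    b = encode_patient(_two_visit_record(["D0009"]), tiny_model, mode=BIDIRECTIONAL)
    assert not np.array_equal(a.pe, b.pe)


def test_encodings_are_finite_over_a_large_random_corpus(tiny_model, tiny_bundle, tiny_vocab):
    from claimpt.encoder import RecordCache, encode_batch
    from claimpt.synthetic_claims import SimulationConfig, simulate_population

    cfg = tiny_bundle.ground_truth.config
    records = simulate_population(
        SimulationConfig(**{**cfg.__dict__, "n_patients": 1000, "seed": 77})
    ).records
    cache = RecordCache(records, tiny_vocab, tiny_model.config)
    for start in range(0, 1000, 250):
        pe, states, _ = encode_batch(
            None, tiny_model, batch=cache.batch(np.arange(start, start + 250))
        )
        assert np.isfinite(pe.data).all() and np.isfinite(states.data).all()


def test_long_histories_keep_the_most_recent_visits(tiny_vocab, tiny_bundle):
    config = EncoderConfig(d=16, n_heads=2, ffn_dim=16, max_seq_len=4)
    params = ModelParameters.init(tiny_vocab.total_size, 8, config, seed=0)
    bind_vocab(params, tiny_vocab)
    visits = [_visit(16000 + 10 * i, [f"D{i:04d}"]) for i in range(9)]
    rec = PatientRecord("p", "F", 2004, visits)
    enc = encode_patient(rec, params)
    assert enc.visit_states.shape[0] == 4


# -- parameter accounting ----------------------------------------------------


@pytest.mark.parametrize("v,k", [(503, 28), (120, 9)])
def test_parameter_count_is_closed_form_in_sizes(v, k):
    params = ModelParameters.init(v, k)
    d = 100
    # independently derived: embeddings + one transformer block + two heads
    emb = v * d + 3 * d + 6 * d + 23 * d
    block = 4 * (d * d + d) + 2 * (d * d) + d + d + 4 * d
    heads = v * (d + 1) + k * (d + 1)
    assert params.parameter_count() == emb + block + heads
    assert params.parameter_count() == expected_parameter_count(v, k)


def test_head_count_does_not_change_parameter_count():
    a = ModelParameters.init(50, 6, EncoderConfig(n_heads=4))
    b = ModelParameters.init(50, 6, EncoderConfig(n_heads=2))
    assert a.parameter_count() == b.parameter_count()


# -- checkpoints --------------------------------------------------------------


def test_checkpoint_roundtrip_preserves_everything(tmp_path, tiny_model, tiny_vocab, tiny_bundle):
    ck = Checkpoint(params=tiny_model, vocab=tiny_vocab, grouper=tiny_bundle.grouper)
    ck.save(tmp_path / "ckpt")
    back = Checkpoint.load(tmp_path / "ckpt")
    assert back.params.state_fingerprint() == tiny_model.state_fingerprint()
    assert back.vocab.fingerprint() == tiny_vocab.fingerprint()


def test_checkpoint_refuses_tampered_vocabulary(tmp_path, tiny_model, tiny_vocab, tiny_bundle):
    ck = Checkpoint(params=tiny_model, vocab=tiny_vocab, grouper=tiny_bundle.grouper)
    ck.save(tmp_path / "ckpt")
    vpath = tmp_path / "ckpt" / "vocab.tsv"
    lines = vpath.read_text().splitlines()
    lines[1] = lines[1].replace("\t0", "\t1", 1)
    vpath.write_text("\n".join(lines) + "\n")
    with pytest.raises(ValueError, match="fingerprint"):
        Checkpoint.load(tmp_path / "ckpt")
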