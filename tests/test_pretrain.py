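"""Objective-function exactness, oracle equivalence, and training-loop
contracts for the pre-training stage."""

import numpy as np
import pytest

from claimpt import _tensor as T
from claimpt.data_model import build_vocabulary
from claimpt.encoder import (
    BIDIRECTIONAL,
    CAUSAL,
    EncoderConfig,
    ModelParameters,
    bind_vocab,
    encode_batch,
    prepare_batch,
)
from claimpt.pretrain import (
    PretrainConfig,
    _l2_penalty,
    cp_loss,
    nvp_loss,
    pretrain,
    train_val_split,
    unigram_nvp_baseline,
)

LN2 = float(np.log(2.0))


def _zero_head_params(vocab_size, n_categories, d=8):
    params = ModelParameters.init(vocab_size, n_categories, EncoderConfig(d=d, n_heads=2, ffn_dim=d), seed=0)
    for name in ("W_n", "b_n", "W_c", "b_c"):
        params.tensors[name].data[:] = 0.0
    return params


# -- closed forms -------------------------------------------------------------


def test_nvp_loss_is_log_vocab_size_at_zero_logits():
    from claimpt.pretrain import _nvp_from_targets

    for V, n_next in ((2, 1), (4, 2)):
        params = _zero_head_params(V, 3)
        states = T.Tensor(np.random.default_rng(0).normal(size=(1, 2, 8)).astype(np.float32))
        w = np.zeros((1, V), dtype=np.float32)
        w[0, :n_next] = 1.0 / n_next
        loss = _nvp_from_targets(states, np.array([0]), np.array([0]), w, params)
        assert abs(float(loss.data) - np.log(V)) < 1e-6


def test_nvp_loss_saturates_when_logits_favour_true_code():
    from claimpt.pretrain import _nvp_from_targets

    params = _zero_head_params(10, 3)
    params.tensors["b_n"].data[4] = 30.0
    states = T.Tensor(np.zeros((1, 1, 8), dtype=np.float32))
    w = np.zeros((1, 10), dtype=np.float32)
    w[0, 4] = 1.0
    loss = _nvp_from_targets(states, np.array([0]), np.array([0]), w, params)
    assert float(loss.data) < 1e-9


def test_cp_loss_is_ln2_per_category_at_zero_logits(tiny_bundle, tiny_vocab):
    params = _zero_head_params(tiny_vocab.total_size, tiny_bundle.grouper.total_categories)
    bind_vocab(params, tiny_vocab)
    records = tiny_bundle.records[:4]
    batch = prepare_batch(records, tiny_vocab, params.config)
    _, states, _ = encode_batch(None, params, mode=BIDIRECTIONAL, batch=batch)
    loss = cp_loss(states, batch.visits, tiny_bundle.grouper, params)
    assert abs(float(loss.data) - LN2) < 1e-6


def test_cp_loss_saturates_on_strongly_scored_category():
    from claimpt.pretrain import _cp_from_targets

    params = _zero_head_params(5, 3)
    params.tensors["b_c"].data[:] = np.array([30.0, -30.0, -30.0])
    states = T.Tensor(np.zeros((1, 1, 8), dtype=np.float32))
    targets = np.array([[1.0, 0.0, 0.0]], dtype=np.float32)
    loss = _cp_from_targets(states, np.array([0]), np.array([0]), targets, params)
    assert float(loss.data) < 1e-9


# -- oracle equivalence -------------------------------------------------------


def _naive_nvp(states, visit_lists, vocab, params):
    """Scalar-loop reference: mean over positions of the mean negative
    log-softmax of each next-visit code."""
    W, b = params.tensors["W_n"].data, params.tensors["b_n"].data
    losses = []
    for bi, vl in enumerate(visit_lists):
        for i in range(len(vl) - 1):
            logits = states.data[bi, i].astype(np.float64) @ W.astype(np.float64) + b
            z = logits - logits.max()
            logp = z - np.log(np.exp(z).sum())
            terms = [
                -logp[vocab.global_index(ch, c)]
                for ch in ("DIAG", "PROC", "DRUG")
                for c in vl[i + 1].codes[ch]
            ]
            losses.append(np.mean(terms))
    return float(np.mean(losses))


def _naive_cp(states, visit_lists, grouper, params):
    W, b = params.tensors["W_c"].data, params.tensors["b_c"].data
    K = params.n_categories
    losses = []
    for bi, vl in enumerate(visit_lists):
        for i, visit in enumerate(vl):
            target = np.zeros(K)
            for ch in ("DIAG", "PROC", "DRUG"):
                for c in visit.codes[ch]:
                    target[grouper.global_category_index(ch, c)] = 1.0
            logits = states.data[bi, i].astype(np.float64) @ W.astype(np.float64) + b
            p = 1 / (1 + np.exp(-logits))
            losses.append(
                np.mean(-(target * np.log(p) + (1 - target) * np.log1p(-p)))
            )
    return float(np.mean(losses))


@pytest.mark.parametrize("seed", range(4))
def test_vectorized_losses_match_naive_summation(tiny_bundle, tiny_vocab, tiny_model, seed):
    rng = np.random.default_rng(seed)
    records = [tiny_bundle.records[i] for i in rng.choice(60, size=8, replace=False)]
    batch = prepare_batch(records, tiny_vocab, tiny_model.config)
    _, states, _ = encode_batch(None, tiny_model, mode=CAUSAL, batch=batch)
    fast = float(nvp_loss(states, batch.visits, tiny_vocab, tiny_model).data)
    slow = _naive_nvp(states, batch.visits, tiny_vocab, tiny_model)
    assert abs(fast - slow) / slow < 1e-5
    _, states_bi, _ = encode_batch(None, tiny_model, mode=BIDIRECTIONAL, batch=batch)
    fast_cp = float(cp_loss(states_bi, batch.visits, tiny_bundle.grouper, tiny_model).data)
    slow_cp = _naive_cp(states_bi, batch.visits, tiny_bundle.grouper, tiny_model)
    assert abs(fast_cp - slow_cp) / slow_cp < 1e-5


def test_nvp_rejects_batches_without_next_visits(tiny_bundle, tiny_vocab, tiny_model):
    from claimpt.data_model import PatientRecord, Visit

    single = [PatientRecord("s", "F", 2004, [Visit(16000, "OP", {"DIAG": {"D0001"}})])]
    batch = prepare_batch(single, tiny_vocab, tiny_model.config)
    _, states, _ = encode_batch(None, tiny_model, mode=CAUSAL, batch=batch)
    with pytest.raises(ValueError):
        nvp_loss(states, batch.visits, tiny_vocab, tiny_model)


# -- training loop ------------------------------------------------------------


@pytest.fixture(scope="module")
def short_training(tiny_bundle, tiny_vocab):
    config = PretrainConfig(max_epochs=4, patience=10, batch_size=20, seed=2)
    params, trace = pretrain(
        tiny_bundle.records, config, tiny_vocab, tiny_bundle.grouper,
        encoder_config=EncoderConfig(d=32, n_heads=4, ffn_dim=32),
    )
    return config, params, trace


def test_training_reduces_nvp_loss_below_initial(short_training, tiny_bundle, tiny_vocab):
    from claimpt.pretrain import evaluate_losses

    config, params, trace = short_training
    # rebuild the frozen initial parameters exactly as the loop derives them
    _, _, rng = train_val_split(len(tiny_bundle.records), config)
    init = ModelParameters.init(
        tiny_vocab.total_size, tiny_bundle.grouper.total_categories,
        EncoderConfig(d=32, n_heads=4, ffn_dim=32), seed=int(rng.integers(2**31)),
    )
    bind_vocab(init, tiny_vocab)
    initial = evaluate_losses(
        tiny_bundle.records, init, config, tiny_vocab, tiny_bundle.grouper
    )
    df = trace.to_frame()
    assert df.train_nvp.iloc[-1] < initial["nvp"]
    assert df.train_total.iloc[-1] < df.train_total.iloc[0]


def test_trace_shape_and_losses_nonnegative(short_training):
    _, _, trace = short_training
    df = trace.to_frame()
    assert trace.stopping_epoch == len(df) <= 4
    assert trace.best_epoch <= trace.stopping_epoch
    for col in ("train_nvp", "train_cp", "val_nvp", "val_cp"):
        assert (df[col] >= 0).all()
    assert df.loc[df.epoch == trace.best_epoch, "val_total"].iloc[0] == df.val_total.min()


def test_disabled_cp_leaves_head_at_initialization(tiny_bundle, tiny_vocab):
    config = PretrainConfig(max_epochs=2, patience=5, batch_size=20, nvp=True, cp=False, seed=2)
    params, trace = pretrain(
        tiny_bundle.records, config, tiny_vocab, tiny_bundle.grouper,
        encoder_config=EncoderConfig(d=32, n_heads=4, ffn_dim=32),
    )
    _, _, rng = train_val_split(len(tiny_bundle.records), config)
    init = ModelParameters.init(
        tiny_vocab.total_size, tiny_bundle.grouper.total_categories,
        EncoderConfig(d=32, n_heads=4, ffn_dim=32), seed=int(rng.integers(2**31)),
    )
    assert np.array_equal(params.tensors["W_c"].data, init.tensors["W_c"].data)
    assert np.array_equal(params.tensors["b_c"].data, init.tensors["b_c"].data)
    assert not any("cp" in k for row in trace.rows for k in row)
    assert not np.array_equal(params.tensors["W_n"].data, init.tensors["W_n"].data)


def test_early_stopping_returns_best_epoch_parameters(tiny_bundle, tiny_vocab):
    # aggressive learning rate forces the validation loss to turn upward
    config = PretrainConfig(
        max_epochs=40, patience=2, batch_size=20, learning_rate=0.02, seed=3
    )
    params, trace = pretrain(
        tiny_bundle.records, config, tiny_vocab, tiny_bundle.grouper,
        encoder_config=EncoderConfig(d=32, n_heads=4, ffn_dim=32),
    )
    assert trace.stopping_epoch < 40
    df = trace.to_frame()
    assert df.val_total.idxmin() + 1 == trace.best_epoch


def test_objective_validation_rejects_empty_sets():
    with pytest.raises(ValueError):
        PretrainConfig(nvp=False, cp=False).validate()


def test_l2_penalty_is_nonneg_and_skips_disabled_heads(tiny_model):
    cfg = PretrainConfig(l2=1e-3, nvp=True, cp=False)
    pen = _l2_penalty(tiny_model, cfg)
    expect = 1e-3 * sum(
        (t.data.astype(np.float64) ** 2).sum()
        for k, t in tiny_model.tensors.items()
        if k not in ("W_c", "b_c")
    )
    assert float(pen.data) >= 0
    assert abs(float(pen.data) - expect) / expect < 1e-5


def test_dropout_off_forward_pass_is_deterministic(tiny_bundle, tiny_vocab, tiny_model):
    batch = prepare_batch(tiny_bundle.records[:5], tiny_vocab, tiny_model.config)
    a, _, _ = encode_batch(None, tiny_model, batch=batch, dropout_p=0.0)
    b, _, _ = encode_batch(None, tiny_model, batch=batch, dropout_p=0.0)
    assert np.array_equal(a.data, b.data)
    c, _, _ = encode_batch(
        None, tiny_model, batch=batch, dropout_p=0.5, rng=np.random.default_rng(0)
    )
    assert not np.array_equal(a.data, c.data)


def test_unigram_baseline_requires_transition_positions(tiny_vocab):
    from claimpt.data_model import PatientRecord, Visit

    rec = PatientRecord("p", "F", 2004, [Visit(16000, "OP", {"DIAG": {"D0001"}})])
    with pytest.raises(ValueError):
        unigram_nvp_baseline([rec], [rec], tiny_vocab)
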