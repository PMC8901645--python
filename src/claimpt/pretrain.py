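"""Unsupervised pre-training: the Next-Visit-Prediction (NVP) and
Categorial-Prediction (CP) objectives and the training loop.

NVP is autoregressive: the hidden state of visit i (under a causal mask)
scores the full code vocabulary with a softmax, and the target is uniform
over the codes actually present in visit i+1 — the per-position loss is the
mean cross-entropy of those codes, so a visit with several codes contributes
the average of their negative log-likelihoods.  CP is a per-visit
multi-label objective: under full attention, each visit's hidden state
predicts the set of grouper categories of its own codes through independent
sigmoids (binary cross-entropy averaged over categories and visits).  The
total loss is NVP + λ·CP over whichever objectives are enabled, optimised
with RMSprop, with dropout, an L2 penalty, and early stopping on the
validation loss.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _tensor as T
from ._optim import RMSprop
from .data_model import CHANNELS, OOV_TOKEN, CategoryGrouper, CodeVocabulary
from .encoder import (
    ALL_CHANNELS,
    BIDIRECTIONAL,
    CAUSAL,
    ChannelFlags,
    EncoderConfig,
    ModelParameters,
    RecordCache,
    bind_vocab,
    encode_batch,
)


@dataclass
class PretrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 100
    max_epochs: int = 1000
    patience: int = 10  # early-stopping patience on validation total loss
    dropout: float = 0.1
    l2: float = 1e-5
    nvp: bool = True
    cp: bool = True
    cp_weight: float = 1.0  # λ mixing the CP loss into the total
    train_fraction: float = 0.8
    rmsprop_decay: float = 0.9
    rmsprop_eps: float = 1e-8
    seed: int = 0

    def validate(self):
        if not (self.nvp or self.cp):
            raise ValueError("at least one objective must be enabled")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be positive")


@dataclass
class TrainingTrace:
    rows: list = field(default_factory=list)  # one dict per epoch
    stopping_epoch: int = 0
    best_epoch: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# -- loss construction -------------------------------------------------------


def _nvp_from_targets(visit_states, pos_b, pos_i, w, params) -> T.Tensor:
    h = visit_states[pos_b, pos_i]  # (N, d)
    logits = h @ params.tensors["W_n"] + params.tensors["b_n"]
    return T.softmax_xent(logits, w).mean()


def _next_visit_targets(visit_lists, vocab: CodeVocabulary):
    """Positions (b, i) with a following visit, plus the uniform target
    distribution over the next visit's codes (all channels)."""
    pos_b, pos_i, rows = [], [], []
    V = vocab.total_size
    for b, vl in enumerate(visit_lists):
        for i in range(len(vl) - 1):
            nxt = vl[i + 1]
            idxs = [
                vocab.global_index(ch, c) for ch in CHANNELS for c in nxt.codes[ch]
            ]
            w = np.zeros(V, dtype=np.float32)
            w[idxs] = np.float32(1.0 / len(idxs))
            pos_b.append(b)
            pos_i.append(i)
            rows.append(w)
    if not rows:
        return None
    return np.asarray(pos_b), np.asarray(pos_i), np.stack(rows)


def nvp_loss(
    visit_states: T.Tensor,
    visit_lists,
    vocab: CodeVocabulary,
    params: ModelParameters,
) -> T.Tensor:
    """Mean next-visit cross-entropy over all contributing positions.

    ``visit_states`` must come from a CAUSAL encode so position i has seen
    only visits ≤ i; records with a single visit contribute nothing.
    """
    targets = _next_visit_targets(visit_lists, vocab)
    if targets is None:
        raise ValueError("batch has no position with a following visit")
    return _nvp_from_targets(visit_states, *targets, params)


def _cp_from_targets(visit_states, pos_b, pos_i, targets, params) -> T.Tensor:
    h = visit_states[pos_b, pos_i]
    logits = h @ params.tensors["W_c"] + params.tensors["b_c"]
    return T.sigmoid_bce(logits, targets).mean()


def _category_targets(visit_lists, cat_table: dict, n_categories: int):
    pos_b, pos_i, rows = [], [], []
    for b, vl in enumerate(visit_lists):
        for i, visit in enumerate(vl):
            t = np.zeros(n_categories, dtype=np.float32)
            for ch in CHANNELS:
                table = cat_table[ch]
                oov = table[OOV_TOKEN]
                for c in visit.codes[ch]:
                    t[table.get(c, oov)] = 1.0
            pos_b.append(b)
            pos_i.append(i)
            rows.append(t)
    return np.asarray(pos_b), np.asarray(pos_i), np.stack(rows)


def cp_loss(
    visit_states: T.Tensor,
    visit_lists,
    grouper: CategoryGrouper,
    params: ModelParameters,
    cat_table: Optional[dict] = None,
) -> T.Tensor:
    """Mean per-category binary cross-entropy of each visit's category set.

    ``visit_states`` should come from a BIDIRECTIONAL encode (the target is
    the visit's own categories, so no causal restriction applies).
    """
    cat_table = cat_table or grouper.category_index_table()
    targets = _category_targets(visit_lists, cat_table, params.n_categories)
    return _cp_from_targets(visit_states, *targets, params)


def unigram_nvp_baseline(train_records, eval_records, vocab: CodeVocabulary) -> float:
    """Cross-entropy of next-visit codes under the training corpus's
    unconditional (unigram) code distribution — the no-context reference the
    sequence model has to beat.  Laplace-smoothed over the global code space."""
    counts = np.ones(vocab.total_size)  # add-one smoothing
    for r in train_records:
        for v in r.visits:
            for ch in CHANNELS:
                for c in v.codes[ch]:
                    counts[vocab.global_index(ch, c)] += 1
    logp = np.log(counts / counts.sum())
    total, n = 0.0, 0
    for r in eval_records:
        for i in range(len(r.visits) - 1):
            nxt = r.visits[i + 1]
            idxs = [
                vocab.global_index(ch, c) for ch in CHANNELS for c in nxt.codes[ch]
            ]
            total += -logp[idxs].mean()
            n += 1
    if n == 0:
        raise ValueError("no next-visit positions in eval records")
    return total / n


# -- cached targets -----------------------------------------------------------


class _TargetCache:
    """Per-record NVP code lists and CP category multi-hots, aligned with a
    RecordCache's truncated visit lists (targets always use all channels)."""

    def __init__(self, cache: RecordCache, vocab, grouper, n_categories):
        cat_table = grouper.category_index_table()
        self.V = vocab.total_size
        self.nvp_flat, self.nvp_counts, self.cp_multi = [], [], []
        for entry in cache.entries:
            vl = entry[5]
            flat, counts = [], np.empty(max(len(vl) - 1, 0), dtype=np.int64)
            for i in range(len(vl) - 1):
                idxs = [
                    vocab.global_index(ch, c)
                    for ch in CHANNELS
                    for c in vl[i + 1].codes[ch]
                ]
                counts[i] = len(idxs)
                flat.extend(idxs)
            self.nvp_flat.append(np.asarray(flat, dtype=np.int64))
            self.nvp_counts.append(counts)
            multi = np.zeros((len(vl), n_categories), dtype=np.float32)
            for i, visit in enumerate(vl):
                for ch in CHANNELS:
                    table = cat_table[ch]
                    oov = table[OOV_TOKEN]
                    for c in visit.codes[ch]:
                        multi[i, table.get(c, oov)] = 1.0
            self.cp_multi.append(multi)

    def nvp_batch(self, indices):
        counts = np.concatenate([self.nvp_counts[i] for i in indices])
        if counts.sum() == 0:
            return None
        flat = np.concatenate([self.nvp_flat[i] for i in indices])
        pos_b = np.repeat(
            np.arange(len(indices)), [len(self.nvp_counts[i]) for i in indices]
        )
        pos_i = np.concatenate(
            [np.arange(len(self.nvp_counts[i])) for i in indices]
        )
        w = np.zeros((len(counts), self.V), dtype=np.float32)
        row_ids = np.repeat(np.arange(len(counts)), counts)
        w[row_ids, flat] = np.repeat(1.0 / counts, counts).astype(np.float32)
        return pos_b, pos_i, w

    def cp_batch(self, indices, batch):
        targets = np.concatenate([self.cp_multi[i] for i in indices])
        return batch.visit_b, batch.visit_t, targets


def train_val_split(n_records: int, config: PretrainConfig):
    """The train/validation patient split pre-training uses (seed-derived)."""
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n_records)
    n_train = int(round(config.train_fraction * n_records))
    if n_train == 0 or n_train == n_records:
        raise ValueError("split leaves an empty train or validation set")
    return order[:n_train], order[n_train:], rng


def evaluate_losses(
    records,
    params: ModelParameters,
    config: PretrainConfig,
    vocab: CodeVocabulary,
    grouper: CategoryGrouper,
    channels: ChannelFlags = ALL_CHANNELS,
) -> dict:
    """Mean NVP/CP losses of fixed parameters over ``records`` (no dropout,
    no updates)."""
    cache = RecordCache(records, vocab, params.config, channels)
    targets = _TargetCache(cache, vocab, grouper, grouper.total_categories)
    order = _length_sorted(np.arange(len(records)), cache.lengths())
    return _epoch_losses(cache, targets, order, params, config, channels, None, None)


# -- training loop -----------------------------------------------------------


def _l2_penalty(params: ModelParameters, config: PretrainConfig) -> T.Tensor:
    """Σ‖θ‖² over tensors that can receive gradients from enabled objectives
    (a disabled objective's head must stay untouched)."""
    total = None
    for name, t in params.tensors.items():
        if not config.nvp and name in ("W_n", "b_n"):
            continue
        if not config.cp and name in ("W_c", "b_c"):
            continue
        term = (t * t).sum()
        total = term if total is None else total + term
    return total * config.l2


def _length_sorted(order: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Group similar sequence lengths to keep attention padding small while
    letting the shuffled order break ties."""
    return order[np.argsort(lengths[order], kind="stable")]


def _epoch_losses(
    cache: RecordCache,
    targets: _TargetCache,
    indices,
    params: ModelParameters,
    config: PretrainConfig,
    channels: ChannelFlags,
    train_rng: Optional[np.random.Generator],
    optimizer: Optional[RMSprop],
):
    """One pass over ``indices`` in minibatches; updates parameters when an
    optimizer is given.  Returns mean per-batch losses."""
    sums = {"nvp": 0.0, "cp": 0.0, "total": 0.0}
    n_batches = 0
    training = optimizer is not None
    dropout = config.dropout if training else 0.0
    for start in range(0, len(indices), config.batch_size):
        idx = indices[start : start + config.batch_size]
        batch = cache.batch(idx)
        parts = []
        if config.nvp:
            nvp_t = targets.nvp_batch(idx)
            if nvp_t is not None:
                _, states, _ = encode_batch(
                    None, params, mode=CAUSAL, channels=channels,
                    dropout_p=dropout, rng=train_rng, batch=batch,
                )
                l_nvp = _nvp_from_targets(states, *nvp_t, params)
                parts.append(l_nvp)
                sums["nvp"] += float(l_nvp.data)
        if config.cp:
            _, states_bi, _ = encode_batch(
                None, params, mode=BIDIRECTIONAL, channels=channels,
                dropout_p=dropout, rng=train_rng, batch=batch,
            )
            l_cp = _cp_from_targets(states_bi, *targets.cp_batch(idx, batch), params)
            parts.append(l_cp * config.cp_weight)
            sums["cp"] += float(l_cp.data)
        if not parts:
            continue
        total = parts[0]
        for p in parts[1:]:
            total = total + p
        if training and config.l2 > 0:
            total = total + _l2_penalty(params, config)
        sums["total"] += float(total.data)
        if training:
            optimizer.zero_grad()
            total.backward()
            optimizer.step()
        n_batches += 1
    if n_batches == 0:
        raise ValueError("no batch produced a loss (all records single-visit?)")
    return {k: v / n_batches for k, v in sums.items()}


def pretrain(
    records,
    config: PretrainConfig,
    vocab: CodeVocabulary,
    grouper: CategoryGrouper,
    encoder_config: Optional[EncoderConfig] = None,
    channels: ChannelFlags = ALL_CHANNELS,
    verbose: bool = False,
):
    """Pre-train a fresh model on an unlabeled corpus.

    Patients are split train/validation by ``config.train_fraction`` using the
    run seed; training stops early when the validation total loss has not
    improved for ``config.patience`` epochs, and the best-validation
    parameters are returned together with the full per-epoch trace.
    """
    config.validate()
    if not records:
        raise ValueError("corpus is empty")
    encoder_config = encoder_config or EncoderConfig()
    train_idx, val_idx, rng = train_val_split(len(records), config)

    params = ModelParameters.init(
        vocab.total_size,
        grouper.total_categories,
        encoder_config,
        seed=int(rng.integers(2**31)),
    )
    bind_vocab(params, vocab)
    cache = RecordCache(records, vocab, encoder_config, channels)
    targets = _TargetCache(cache, vocab, grouper, grouper.total_categories)
    lengths = cache.lengths()
    val_order = _length_sorted(val_idx, lengths)
    optimizer = RMSprop(
        params.tensors, config.learning_rate, config.rmsprop_decay, config.rmsprop_eps
    )
    trace = TrainingTrace()
    best_val, best_state, best_epoch, bad_epochs = np.inf, None, 0, 0
    for epoch in range(1, config.max_epochs + 1):
        t0 = time.perf_counter()
        epoch_rng = np.random.default_rng([config.seed, epoch])
        train_order = _length_sorted(
            train_idx[epoch_rng.permutation(len(train_idx))], lengths
        )
        train_losses = _epoch_losses(
            cache, targets, train_order, params, config, channels, epoch_rng, optimizer
        )
        val_losses = _epoch_losses(
            cache, targets, val_order, params, config, channels, None, None
        )
        row = {"epoch": epoch, "seconds": time.perf_counter() - t0}
        for split, losses in (("train", train_losses), ("val", val_losses)):
            if config.nvp:
                row[f"{split}_nvp"] = losses["nvp"]
            if config.cp:
                row[f"{split}_cp"] = losses["cp"]
            row[f"{split}_total"] = losses["total"]
        trace.rows.append(row)
        if verbose:
            print(
                f"epoch {epoch}: train {train_losses['total']:.4f} "
                f"val {val_losses['total']:.4f}"
            )
        if val_losses["total"] < best_val - 1e-6:
            best_val = val_losses["total"]
            best_epoch = epoch
            best_state = {k: t.data.copy() for k, t in params.tensors.items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break
    trace.stopping_epoch = len(trace.rows)
    trace.best_epoch = best_epoch
    if best_state is not None:
        for k, t in params.tensors.items():
            t.data = best_state[k]
    return params, trace
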