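"""Task-aware adaptation of a pre-trained body to a binary cohort task.

Four modes ship:

* ``FULL_FINETUNE`` — a fresh linear head on the patient representation
  ``pe``; head *and* body are updated.
* ``PROBE_START`` — the head is trained on frozen ``pe`` (a linear probe of
  the first-token representation).
* ``PROBE_POOL`` — the head is trained on the frozen element-wise max (or
  mean) of the visit hidden states.
* ``FROM_SCRATCH`` — the body is randomly re-initialised and trained
  end-to-end on the cohort alone: the no-pre-training control.

Each repeat re-splits the cohort train/test with a repeat-specific seed,
optimises the two-class cross-entropy for a fixed number of epochs, and
scores the held-out patients; probe modes never touch the body (asserted
bitwise in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _tensor as T
from ._optim import RMSprop
from .data_model import CodeVocabulary
from .encoder import (
    BIDIRECTIONAL,
    ChannelFlags,
    Checkpoint,
    ModelParameters,
    RecordCache,
    bind_vocab,
    encode_batch,
)
from .evaluation import auc

FULL_FINETUNE = "FULL_FINETUNE"
PROBE_START = "PROBE_START"
PROBE_POOL = "PROBE_POOL"
FROM_SCRATCH = "FROM_SCRATCH"
MODES = (FULL_FINETUNE, PROBE_START, PROBE_POOL, FROM_SCRATCH)

_NEG = np.float32(-1e9)


class FinetuneHead:
    """The added linear output layer: d × 2 weights plus 2 biases — the only
    new parameters fine-tuning introduces."""

    def __init__(self, d: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        lim = np.sqrt(6.0 / (d + 2))
        self.W = T.Tensor(
            rng.uniform(-lim, lim, (d, 2)).astype(np.float32), requires_grad=True
        )
        self.b = T.Tensor(np.zeros(2, dtype=np.float32), requires_grad=True)

    def tensors(self) -> dict:
        return {"head.W": self.W, "head.b": self.b}

    def parameter_count(self) -> int:
        return self.W.data.size + self.b.data.size

    def logits(self, rep: T.Tensor) -> T.Tensor:
        return rep @ self.W + self.b


@dataclass
class FinetuneConfig:
    mode: str = FULL_FINETUNE
    epochs: int = 20
    lr_body: float = 3e-4
    lr_head: float = 1e-2
    batch_size: int = 64
    head_warmup_epochs: int = 5  # head-only epochs before joint updates
    train_fraction: float = 0.7
    repeats: int = 5
    pool: str = "max"  # PROBE_POOL operator: "max" or "mean"
    channels: ChannelFlags = field(default_factory=ChannelFlags)
    include_visits: bool = True  # False → demographics-only encoding
    seed: int = 0

    def validate(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.epochs < 1:
            raise ValueError("epochs must be ≥ 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.pool not in ("max", "mean"):
            raise ValueError("pool must be 'max' or 'mean'")


@dataclass
class FinetuneResult:
    mode: str
    aucs: list
    mean_auc: float
    std_auc: float
    predictions: pd.DataFrame  # columns: repeat, patient_id, score, label
    params: ModelParameters  # body used in the last repeat
    head: FinetuneHead  # head trained in the last repeat


def _pooled_states(states: T.Tensor, visit_mask: np.ndarray, op: str) -> T.Tensor:
    if op == "max":
        penalty = np.where(visit_mask, np.float32(0.0), _NEG)[..., None]
        return (states + T.Tensor(penalty)).max(axis=1)
    keep = visit_mask[..., None].astype(np.float32)
    denom = visit_mask.sum(axis=1, keepdims=True).astype(np.float32)
    return (states * T.Tensor(keep)).sum(axis=1) / T.Tensor(denom)


def _representation(
    records,
    params: ModelParameters,
    mode: str,
    config: FinetuneConfig,
    batch=None,
) -> T.Tensor:
    pe, states, b = encode_batch(
        records,
        params,
        mode=BIDIRECTIONAL,
        channels=config.channels,
        include_visits=config.include_visits,
        batch=batch,
    )
    if mode == PROBE_POOL:
        return _pooled_states(states, b.visit_mask, config.pool)
    return pe


def _check_vocab(checkpoint: Checkpoint, vocab: Optional[CodeVocabulary]) -> None:
    if vocab is not None and vocab.fingerprint() != checkpoint.vocab.fingerprint():
        raise ValueError(
            "vocabulary fingerprint does not match the checkpoint; refusing to "
            "score codes against a different index"
        )


def predict_proba(
    record,
    checkpoint: Checkpoint,
    head: FinetuneHead,
    mode: str = FULL_FINETUNE,
    config: Optional[FinetuneConfig] = None,
    vocab: Optional[CodeVocabulary] = None,
) -> np.ndarray:
    """Class probabilities (P(y=0), P(y=1)) for one patient; sums to 1."""
    _check_vocab(checkpoint, vocab)
    config = config or FinetuneConfig(mode=mode)
    rep = _representation([record], checkpoint.params, mode, config)
    logits = head.logits(rep).data[0].astype(np.float64)
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def _train_head_on_reps(reps: np.ndarray, labels: np.ndarray, head, config):
    """Probe head: an L2-regularised logistic fit on the frozen
    representations, solved to convergence and written into the head."""
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(max_iter=5000).fit(reps.astype(np.float64), labels)
    head.W.data[:] = 0.0
    head.W.data[:, 1] = clf.coef_[0].astype(np.float32)
    head.b.data[:] = 0.0
    head.b.data[1] = np.float32(clf.intercept_[0])


def _train_end_to_end(cache, indices, labels, params, head, config, rng):
    """Joint training with a head warm-up: the fresh head is first fitted to
    convergence on the frozen initial representations (so joint updates start
    from a sensible head rather than noise), then body and head are updated
    together for the remaining epochs."""
    if config.head_warmup_epochs > 0:
        reps = np.concatenate(
            [
                _representation(
                    None, params, config.mode, config,
                    batch=cache.batch(indices[s : s + 500]),
                ).data
                for s in range(0, len(indices), 500)
            ]
        )
        _train_head_on_reps(reps, labels, head, config)
    body_opt = RMSprop(params.tensors, config.lr_body)
    head_opt = RMSprop(head.tensors(), config.lr_head)
    onehot = np.eye(2, dtype=np.float32)[labels]
    for epoch in range(max(config.epochs - config.head_warmup_epochs, 1)):
        order = rng.permutation(len(indices))
        for start in range(0, len(indices), config.batch_size):
            sel = order[start : start + config.batch_size]
            batch = cache.batch(indices[sel])
            rep = _representation(None, params, config.mode, config, batch=batch)
            loss = T.softmax_xent(head.logits(rep), onehot[sel]).mean()
            body_opt.zero_grad()
            head_opt.zero_grad()
            loss.backward()
            body_opt.step()
            head_opt.step()


def _scores(cache, indices, params, head, config) -> np.ndarray:
    out = np.empty(len(indices))
    for start in range(0, len(indices), 500):
        sel = indices[start : start + 500]
        batch = cache.batch(sel)
        rep = _representation(None, params, config.mode, config, batch=batch)
        logits = head.logits(rep).data.astype(np.float64)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        out[start : start + len(sel)] = (e / e.sum(axis=1, keepdims=True))[:, 1]
    return out


def finetune(
    cohort,
    checkpoint: Checkpoint,
    config: FinetuneConfig,
    vocab: Optional[CodeVocabulary] = None,
) -> FinetuneResult:
    """Run the repeat-averaged fine-tuning protocol on a labeled cohort."""
    config.validate()
    _check_vocab(checkpoint, vocab)
    examples = list(cohort)
    labels = np.asarray([ex.label for ex in examples], dtype=np.int64)
    if len(np.unique(labels)) < 2:
        raise ValueError("cohort must contain both classes")
    records = [ex.record for ex in examples]
    base_params = checkpoint.params
    cache = RecordCache(
        records, checkpoint.vocab, base_params.config, config.channels
    )
    n = len(records)
    n_train = int(round(config.train_fraction * n))
    rows, aucs = [], []
    frozen = config.mode in (PROBE_START, PROBE_POOL)
    if frozen:
        # body is fixed: compute representations once, train heads on them
        all_reps = np.concatenate(
            [
                _representation(
                    None, base_params, config.mode, config, batch=cache.batch(sel)
                ).data
                for sel in np.array_split(np.arange(n), max(1, n // 500))
            ]
        )
    params = base_params
    head = None
    for rep_i in range(config.repeats):
        r_rng = np.random.default_rng([config.seed, rep_i])
        order = r_rng.permutation(n)
        train_sel, test_sel = order[:n_train], order[n_train:]
        if len(np.unique(labels[train_sel])) < 2 or len(np.unique(labels[test_sel])) < 2:
            order = np.concatenate(
                [np.flatnonzero(labels == 1), np.flatnonzero(labels == 0)]
            )
            r_rng.shuffle(order)
            train_sel, test_sel = order[:n_train], order[n_train:]
        head = FinetuneHead(base_params.config.d, seed=int(r_rng.integers(2**31)))
        if config.mode == FULL_FINETUNE:
            params = base_params.copy()
            bind_vocab(params, checkpoint.vocab)
            _train_end_to_end(cache, train_sel, labels[train_sel], params, head, config, r_rng)
            scores = _scores(cache, test_sel, params, head, config)
        elif config.mode == FROM_SCRATCH:
            params = ModelParameters.init(
                base_params.vocab_size,
                base_params.n_categories,
                base_params.config,
                seed=int(r_rng.integers(2**31)),
            )
            bind_vocab(params, checkpoint.vocab)
            _train_end_to_end(cache, train_sel, labels[train_sel], params, head, config, r_rng)
            scores = _scores(cache, test_sel, params, head, config)
        else:
            _train_head_on_reps(all_reps[train_sel], labels[train_sel], head, config)
            logits = (
                all_reps[test_sel] @ head.W.data + head.b.data
            ).astype(np.float64)
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            scores = (e / e.sum(axis=1, keepdims=True))[:, 1]
        aucs.append(auc(scores, labels[test_sel]))
        for j, sel in enumerate(test_sel):
            rows.append(
                {
                    "repeat": rep_i,
                    "patient_id": records[sel].patient_id,
                    "score": float(scores[j]),
                    "label": int(labels[sel]),
                }
            )
    return FinetuneResult(
        mode=config.mode,
        aucs=aucs,
        mean_auc=float(np.mean(aucs)),
        std_auc=float(np.std(aucs)),
        predictions=pd.DataFrame(rows),
        params=params,
        head=head,
    )
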