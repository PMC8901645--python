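"""Metrics, repeat-averaged experiment runners (input-channel and objective
ablations, cross-corpus transfer), bag-of-codes logistic baselines, and
embedding export."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .data_model import CHANNELS, CategoryGrouper, CodeVocabulary
from .encoder import (
    ALL_CHANNELS,
    BIDIRECTIONAL,
    ChannelFlags,
    Checkpoint,
    ModelParameters,
    RecordCache,
    encode_batch,
)


def auc(scores, labels) -> float:
    """Area under the ROC curve: the probability a random positive outscores
    a random negative, ties counting one half (Mann–Whitney U / (n₊·n₋))."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


@dataclass
class ExperimentResult:
    name: str
    aucs: list
    mean_auc: float
    std_auc: float
    manifest: dict

    @classmethod
    def from_aucs(cls, name, aucs, manifest=None):
        return cls(
            name=name,
            aucs=list(map(float, aucs)),
            mean_auc=float(np.mean(aucs)),
            std_auc=float(np.std(aucs)),
            manifest=manifest or {},
        )


def _cohort_fingerprint(cohort) -> str:
    h = hashlib.sha256()
    for ex in cohort:
        h.update(f"{ex.record.patient_id}:{ex.label}\n".encode())
    return h.hexdigest()


# -- CP head diagnostics -----------------------------------------------------


def cp_category_auc(
    params: ModelParameters,
    records,
    vocab: CodeVocabulary,
    grouper: CategoryGrouper,
    channels: ChannelFlags = ALL_CHANNELS,
    batch_size: int = 200,
) -> float:
    """Macro-averaged one-vs-rest AUC of the CP head over categories with
    both outcomes present — how well visit hidden states recover their own
    category sets."""
    from .pretrain import _category_targets

    cache = RecordCache(records, vocab, params.config, channels)
    cat_table = grouper.category_index_table()
    all_logits, all_targets = [], []
    for start in range(0, len(records), batch_size):
        batch = cache.batch(np.arange(start, min(start + batch_size, len(records))))
        _, states, _ = encode_batch(
            None, params, mode=BIDIRECTIONAL, channels=channels, batch=batch
        )
        pos_b, pos_i, targets = _category_targets(
            batch.visits, cat_table, params.n_categories
        )
        h = states.data[pos_b, pos_i]
        all_logits.append(h @ params.tensors["W_c"].data + params.tensors["b_c"].data)
        all_targets.append(targets)
    logits = np.concatenate(all_logits)
    targets = np.concatenate(all_targets)
    per_cat = [
        roc_auc_score(targets[:, k], logits[:, k])
        for k in range(targets.shape[1])
        if 0 < targets[:, k].sum() < len(targets)
    ]
    if not per_cat:
        raise ValueError("no category has both outcomes present")
    return float(np.mean(per_cat))


# -- experiment runners ------------------------------------------------------

def _fresh_params(vocab, grouper, encoder_config=None, seed: int = 0):
    from .encoder import EncoderConfig, bind_vocab

    params = ModelParameters.init(
        vocab.total_size,
        grouper.total_categories,
        encoder_config or EncoderConfig(),
        seed=seed,
    )
    return bind_vocab(params, vocab)


INPUT_ARMS = (
    ("demographics", dict(include_visits=False)),
    ("+codes", dict(channels=ChannelFlags(util=False, date=False))),
    ("+utilization", dict(channels=ChannelFlags(date=False))),
    ("+date", dict(channels=ChannelFlags())),
)


def run_ablation_inputs(
    records,
    grouper: CategoryGrouper,
    vocab: CodeVocabulary,
    cohort,
    pretrain_config,
    finetune_config,
    encoder_config=None,
) -> dict:
    """One model per cumulative input-channel set, shared seeds across arms.

    The demographics-only arm has no visit tokens to pre-train on, so it is
    trained from scratch on the cohort; every other arm pre-trains with its
    channel set and fully fine-tunes.
    """
    from .finetune import FROM_SCRATCH, FULL_FINETUNE, finetune
    from .pretrain import pretrain

    results = {}
    for name, overrides in INPUT_ARMS:
        ft = replace(finetune_config, **overrides)
        if not ft.include_visits:
            ft = replace(ft, mode=FROM_SCRATCH)
            ckpt = Checkpoint(
                params=_fresh_params(vocab, grouper, encoder_config),
                vocab=vocab,
                grouper=grouper,
            )
        else:
            ft = replace(ft, mode=FULL_FINETUNE)
            params, _ = pretrain(
                records, pretrain_config, vocab, grouper,
                encoder_config=encoder_config, channels=ft.channels,
            )
            ckpt = Checkpoint(params=params, vocab=vocab, grouper=grouper)
        res = finetune(cohort, ckpt, ft)
        results[name] = ExperimentResult.from_aucs(
            name, res.aucs, {"arm": name, "cohort": _cohort_fingerprint(cohort)}
        )
    return results


OBJECTIVE_ARMS = (
    ("NVP", dict(nvp=True, cp=False)),
    ("CP", dict(nvp=False, cp=True)),
    ("NVP+CP", dict(nvp=True, cp=True)),
)


def run_ablation_objectives(
    records,
    grouper: CategoryGrouper,
    vocab: CodeVocabulary,
    cohort,
    pretrain_config,
    finetune_config,
    encoder_config=None,
) -> dict:
    """Pre-train under each objective set (shared seeds), fine-tune each."""
    from .finetune import FULL_FINETUNE, finetune
    from .pretrain import pretrain

    results = {}
    for name, flags in OBJECTIVE_ARMS:
        pt = replace(pretrain_config, **flags)
        params, _ = pretrain(
            records, pt, vocab, grouper, encoder_config=encoder_config
        )
        ckpt = Checkpoint(params=params, vocab=vocab, grouper=grouper)
        ft = replace(finetune_config, mode=FULL_FINETUNE)
        res = finetune(cohort, ckpt, ft)
        results[name] = ExperimentResult.from_aucs(
            name, res.aucs, {"objectives": name}
        )
    return results


@dataclass
class TransferComparison:
    overlap: float
    pretrained: ExperimentResult
    from_scratch: ExperimentResult
    absolute_gain: float
    relative_gain: float  # (AUC_pt − AUC_scratch) / AUC_scratch


def run_transfer(
    config_a,
    config_b,
    overlaps,
    pretrain_config,
    finetune_config,
    n_cases: int,
    control_ratio: float = 2.0,
    encoder_config=None,
    min_count: int = 1,
) -> dict:
    """Pre-train on corpus A once, then for each overlap level fine-tune on a
    downstream cohort drawn from corpus B (whose code distributions share
    `overlap` of A's) and compare with training from scratch on B alone."""
    from .data_model import build_vocabulary, cohort_from_labels
    from .finetune import FROM_SCRATCH, FULL_FINETUNE, finetune
    from .pretrain import pretrain
    from .synthetic_claims import make_transfer_pair

    results = {}
    ckpt = None
    for overlap in overlaps:
        bundle_a, bundle_b = make_transfer_pair(config_a, config_b, overlap)
        if ckpt is None:  # corpus A does not depend on the overlap level
            vocab = build_vocabulary(bundle_a.records, min_count=min_count)
            params, _ = pretrain(
                bundle_a.records, pretrain_config, vocab, bundle_a.grouper,
                encoder_config=encoder_config,
            )
            ckpt = Checkpoint(params=params, vocab=vocab, grouper=bundle_a.grouper)
        cohort = cohort_from_labels(
            bundle_b.records, n_cases, control_ratio, seed=finetune_config.seed
        )
        full = finetune(cohort, ckpt, replace(finetune_config, mode=FULL_FINETUNE))
        scratch = finetune(cohort, ckpt, replace(finetune_config, mode=FROM_SCRATCH))
        results[overlap] = TransferComparison(
            overlap=overlap,
            pretrained=ExperimentResult.from_aucs(f"pretrained@{overlap}", full.aucs),
            from_scratch=ExperimentResult.from_aucs(f"scratch@{overlap}", scratch.aucs),
            absolute_gain=full.mean_auc - scratch.mean_auc,
            relative_gain=(full.mean_auc - scratch.mean_auc) / scratch.mean_auc,
        )
    return results


# -- baselines ---------------------------------------------------------------

SPARSE_COUNTS = "SPARSE_COUNTS"
DENSE_CATEGORY_COUNTS = "DENSE_CATEGORY_COUNTS"


def _count_features(records, vocab, grouper, mode):
    if mode == SPARSE_COUNTS:
        width = vocab.total_size
        X = np.zeros((len(records), width))
        for i, r in enumerate(records):
            for v in r.visits:
                for ch in CHANNELS:
                    for c in v.codes[ch]:
                        X[i, vocab.global_index(ch, c)] += 1
    elif mode == DENSE_CATEGORY_COUNTS:
        table = grouper.category_index_table()
        width = grouper.total_categories
        X = np.zeros((len(records), width))
        for i, r in enumerate(records):
            for v in r.visits:
                for ch in CHANNELS:
                    oov = table[ch]["<OOV>"]
                    for c in v.codes[ch]:
                        X[i, table[ch].get(c, oov)] += 1
    else:
        raise ValueError(f"unknown baseline mode {mode!r}")
    return X


def logistic_baseline(
    cohort,
    vocab: CodeVocabulary,
    grouper: CategoryGrouper,
    mode: str = SPARSE_COUNTS,
    train_fraction: float = 0.7,
    repeats: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> ExperimentResult:
    """L2-regularised logistic regression on per-patient code counts
    (SPARSE) or grouper-aggregated category counts (DENSE), under the same
    split/repeat protocol as fine-tuning."""
    examples = list(cohort)
    y = np.asarray([ex.label for ex in examples])
    X = _count_features([ex.record for ex in examples], vocab, grouper, mode)
    n_train = int(round(train_fraction * len(y)))
    aucs = []
    for rep in range(repeats):
        rng = np.random.default_rng([seed, rep])
        order = rng.permutation(len(y))
        tr, te = order[:n_train], order[n_train:]
        clf = LogisticRegression(C=C, max_iter=2000)
        clf.fit(X[tr], y[tr])
        aucs.append(auc(clf.predict_proba(X[te])[:, 1], y[te]))
    return ExperimentResult.from_aucs(
        f"LR:{mode}", aucs, {"mode": mode, "n_features": X.shape[1]}
    )


# -- embedding export --------------------------------------------------------


def export_embeddings(
    checkpoint: Checkpoint,
    kind: str = "codes",
    channel: str = "DIAG",
    cohort=None,
    path=None,
) -> pd.DataFrame:
    """Exact embedding tables for external projection (e.g. t-SNE).

    ``codes`` → the embedding rows of one channel's vocabulary (identifier =
    code string); ``patients`` → ``pe`` under bidirectional encoding
    (identifier = patient id).  Re-export from the same checkpoint is
    bit-identical.
    """
    params = checkpoint.params
    if kind == "codes":
        vocab = checkpoint.vocab
        off = vocab.channel_offset(channel)
        labels = [
            c for c, _ in sorted(vocab.index[channel].items(), key=lambda kv: kv[1])
        ]
        rows = params.tensors["E_code"].data[off : off + len(labels)]
        df = pd.DataFrame(rows, copy=True)
        df.insert(0, "identifier", labels)
    elif kind == "patients":
        if cohort is None:
            raise ValueError("patient export requires a cohort")
        records = [getattr(ex, "record", ex) for ex in cohort]
        cache = RecordCache(records, checkpoint.vocab, params.config)
        pes = []
        for start in range(0, len(records), 500):
            sel = np.arange(start, min(start + 500, len(records)))
            pe, _, _ = encode_batch(None, params, batch=cache.batch(sel))
            pes.append(pe.data)
        df = pd.DataFrame(np.concatenate(pes), copy=True)
        df.insert(0, "identifier", [r.patient_id for r in records])
    else:
        raise ValueError(f"unknown export kind {kind!r}")
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
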