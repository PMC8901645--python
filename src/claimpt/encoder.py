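"""The claims-sequence encoder.

Every visit is embedded by stacking the embedding rows of its codes (one
shared table over the concatenated DIAG/PROC/DRUG index space), a visit-type
row, and a date-bucket row for the gap since the previous visit, then taking
the element-wise maximum — one d-vector per visit, invariant to code order.
A demographic token (gender × age-bucket one-hot, linearly projected) is
prepended, and a stack of post-norm transformer layers (multi-head
self-attention, position-wise feed-forward, residual + layer normalisation)
produces the patient representation ``pe`` (position 0) and per-visit hidden
states.  Attention is either CAUSAL (position i sees ≤ i; used by the
autoregressive objective) or BIDIRECTIONAL (all-to-all; used everywhere a
whole-sequence summary is wanted).

Internally visits are pooled over a flat row list with a segment max rather
than a padded (batch, visit, code, d) block — the code-count distribution is
long-tailed, so padding to the max would dominate memory and time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import _tensor as T
from .data_model import (
    CHANNELS,
    CategoryGrouper,
    CodeVocabulary,
    PatientRecord,
    Visit,
)

CAUSAL = "CAUSAL"
BIDIRECTIONAL = "BIDIRECTIONAL"

# inter-visit gap buckets in days: [0], [1,7], [8,30], [31,90], [91,365], >365
_GAP_EDGES = (0, 7, 30, 90, 365)
N_DATE_BUCKETS = len(_GAP_EDGES) + 1

_GENDER_IDX = {"M": 0, "F": 1, "U": 2}
N_AGE_BUCKETS = 20  # annual 0–18 plus a 19+ bucket
DEMO_WIDTH = len(_GENDER_IDX) + N_AGE_BUCKETS

_NEG = np.float32(-1e9)
_TYPE_ORDER = {"IP": 0, "OP": 1, "RX": 2}


def date_bucket(gap_days: int) -> int:
    """Bucket index of a non-negative inter-visit gap (first visit → 0)."""
    for i, edge in enumerate(_GAP_EDGES):
        if gap_days <= edge:
            return i
    return len(_GAP_EDGES)


def age_bucket(age_years: float) -> int:
    if age_years < 0:
        raise ValueError("age must be non-negative")
    return min(int(age_years), N_AGE_BUCKETS - 1)


def demographic_onehot(gender: str, age_years: float) -> np.ndarray:
    vec = np.zeros(DEMO_WIDTH, dtype=np.float32)
    vec[_GENDER_IDX[gender]] = 1.0
    vec[len(_GENDER_IDX) + age_bucket(age_years)] = 1.0
    return vec


@dataclass
class ChannelFlags:
    """Which input channels contribute rows to the visit max-pool."""

    diag: bool = True
    proc: bool = True
    drug: bool = True
    util: bool = True  # visit-type embedding
    date: bool = True  # gap-bucket embedding

    def code_channels(self):
        return [
            ch for ch, on in zip(CHANNELS, (self.diag, self.proc, self.drug)) if on
        ]


ALL_CHANNELS = ChannelFlags()


@dataclass
class EncoderConfig:
    d: int = 100
    n_heads: int = 4
    n_layers: int = 1
    ffn_dim: int = 100
    max_seq_len: int = 128  # visits; longer histories drop the oldest
    layernorm_eps: float = 1e-5

    def validate(self):
        if self.d % self.n_heads != 0:
            raise ValueError("d must be divisible by n_heads")


class ModelParameters:
    """All trainable arrays: embedding tables, transformer layers, and the
    next-visit-prediction (NVP) and categorial-prediction (CP) heads."""

    def __init__(self, config: EncoderConfig, vocab_size: int, n_categories: int):
        config.validate()
        self.config = config
        self.vocab_size = vocab_size
        self.n_categories = n_categories
        self.tensors: dict = {}
        self.vocab: Optional[CodeVocabulary] = None

    @classmethod
    def init(
        cls,
        vocab_size: int,
        n_categories: int,
        config: Optional[EncoderConfig] = None,
        seed: int = 0,
    ) -> "ModelParameters":
        config = config or EncoderConfig()
        self = cls(config, vocab_size, n_categories)
        rng = np.random.default_rng(seed)
        d, f = config.d, config.ffn_dim

        def normal(*shape, scale=0.02):
            return T.Tensor(
                rng.normal(0.0, scale, shape).astype(np.float32), requires_grad=True
            )

        def xavier(n_in, n_out):
            lim = np.sqrt(6.0 / (n_in + n_out))
            return T.Tensor(
                rng.uniform(-lim, lim, (n_in, n_out)).astype(np.float32),
                requires_grad=True,
            )

        def zeros(*shape):
            return T.Tensor(np.zeros(shape, dtype=np.float32), requires_grad=True)

        def ones(*shape):
            return T.Tensor(np.ones(shape, dtype=np.float32), requires_grad=True)

        p = self.tensors
        p["E_code"] = normal(vocab_size, d)
        p["E_type"] = normal(3, d)
        p["E_date"] = normal(N_DATE_BUCKETS, d)
        p["W_demo"] = xavier(DEMO_WIDTH, d)
        for l in range(config.n_layers):
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[f"L{l}.{name}"] = xavier(d, d)
                p[f"L{l}.b{name[1]}"] = zeros(d)
            p[f"L{l}.ln1_g"], p[f"L{l}.ln1_b"] = ones(d), zeros(d)
            p[f"L{l}.W1"], p[f"L{l}.b1"] = xavier(d, f), zeros(f)
            p[f"L{l}.W2"], p[f"L{l}.b2"] = xavier(f, d), zeros(d)
            p[f"L{l}.ln2_g"], p[f"L{l}.ln2_b"] = ones(d), zeros(d)
        p["W_n"] = xavier(d, vocab_size)
        p["b_n"] = zeros(vocab_size)
        p["W_c"] = xavier(d, n_categories)
        p["b_c"] = zeros(n_categories)
        return self

    # -- bookkeeping --------------------------------------------------------

    def parameters(self) -> dict:
        return self.tensors

    def parameter_count(self) -> int:
        return sum(t.data.size for t in self.tensors.values())

    def copy(self) -> "ModelParameters":
        out = ModelParameters(self.config, self.vocab_size, self.n_categories)
        out.tensors = {
            k: T.Tensor(v.data.copy(), requires_grad=True)
            for k, v in self.tensors.items()
        }
        out.vocab = self.vocab
        return out

    def state_fingerprint(self) -> str:
        h = hashlib.sha256()
        for k in sorted(self.tensors):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.tensors[k].data).tobytes())
        return h.hexdigest()


def expected_parameter_count(
    vocab_size: int, n_categories: int, config: Optional[EncoderConfig] = None
) -> int:
    """Closed-form size of the parameterisation (the attention-head count
    does not add parameters; the per-head split is a reshape)."""
    c = config or EncoderConfig()
    d, f = c.d, c.ffn_dim
    emb = vocab_size * d + 3 * d + N_DATE_BUCKETS * d + DEMO_WIDTH * d
    layer = 4 * (d * d + d) + (d * f + f) + (f * d + d) + 2 * (2 * d)
    heads = vocab_size * (d + 1) + n_categories * (d + 1)
    return emb + c.n_layers * layer + heads


@dataclass
class PatientEncoding:
    pe: np.ndarray  # (d,)
    visit_states: np.ndarray  # (T, d)


# -- batch preparation -------------------------------------------------------


@dataclass
class EncodedBatch:
    """Flat index arrays feeding the differentiable forward pass: one row
    list over all real visits (length M), plus their (patient, position)
    coordinates in the padded grid."""

    flat_code_idx: np.ndarray  # (Ncode,) global code indices, visit-major
    code_seg: np.ndarray  # (Ncode,) visit serial 0..M−1, sorted
    type_idx: np.ndarray  # (M,)
    bucket_idx: np.ndarray  # (M,)
    visit_b: np.ndarray  # (M,) patient row of each visit
    visit_t: np.ndarray  # (M,) position of each visit
    visit_mask: np.ndarray  # (B, Tmax) bool
    demo: np.ndarray  # (B, DEMO_WIDTH)
    visits: list  # per record: the (possibly truncated) visit lists


def _truncate(visits, max_len):
    return visits[-max_len:] if len(visits) > max_len else visits


class RecordCache:
    """Per-record index arrays computed once so epoch loops only assemble
    batches instead of re-resolving codes against the vocabulary."""

    def __init__(
        self,
        records,
        vocab: CodeVocabulary,
        config: EncoderConfig,
        channels: ChannelFlags = ALL_CHANNELS,
    ):
        self.config = config
        self.channels = channels
        code_channels = channels.code_channels()
        self.entries = []
        for rec in records:
            vl = _truncate(rec.visits, config.max_seq_len)
            codes, counts = [], np.empty(len(vl), dtype=np.int64)
            types = np.empty(len(vl), dtype=np.int64)
            buckets = np.empty(len(vl), dtype=np.int64)
            prev = None
            for i, visit in enumerate(vl):
                idxs = [
                    vocab.global_index(ch, c)
                    for ch in code_channels
                    for c in sorted(visit.codes[ch])
                ]
                if not idxs and not (channels.util or channels.date):
                    raise ValueError(
                        "visit contributes no rows under the enabled channels"
                    )
                codes.append(idxs)
                counts[i] = len(idxs)
                types[i] = _TYPE_ORDER[visit.visit_type]
                gap = 0 if prev is None else visit.service_date - prev
                buckets[i] = date_bucket(max(gap, 0))
                prev = visit.service_date
            flat = np.asarray(
                [c for visit_codes in codes for c in visit_codes], dtype=np.int64
            )
            demo = demographic_onehot(rec.gender, max(rec.age_at_first_visit, 0.0))
            self.entries.append((flat, counts, types, buckets, demo, vl))

    def __len__(self):
        return len(self.entries)

    def lengths(self) -> np.ndarray:
        return np.asarray([len(e[5]) for e in self.entries])

    def batch(self, indices) -> EncodedBatch:
        entries = [self.entries[i] for i in indices]
        B = len(entries)
        Tmax = max(len(e[5]) for e in entries)
        visit_mask = np.zeros((B, Tmax), dtype=bool)
        demo = np.empty((B, DEMO_WIDTH), dtype=np.float32)
        visits = []
        flat_parts, count_parts, type_parts, bucket_parts = [], [], [], []
        vb, vt = [], []
        for b, (flat, counts, types, buckets, dvec, vl) in enumerate(entries):
            t = len(vl)
            visit_mask[b, :t] = True
            demo[b] = dvec
            visits.append(vl)
            flat_parts.append(flat)
            count_parts.append(counts)
            type_parts.append(types)
            bucket_parts.append(buckets)
            vb.append(np.full(t, b, dtype=np.int64))
            vt.append(np.arange(t, dtype=np.int64))
        counts = np.concatenate(count_parts)
        return EncodedBatch(
            flat_code_idx=np.concatenate(flat_parts),
            code_seg=np.repeat(np.arange(len(counts), dtype=np.int64), counts),
            type_idx=np.concatenate(type_parts),
            bucket_idx=np.concatenate(bucket_parts),
            visit_b=np.concatenate(vb),
            visit_t=np.concatenate(vt),
            visit_mask=visit_mask,
            demo=demo,
            visits=visits,
        )


def prepare_batch(
    records,
    vocab: CodeVocabulary,
    config: EncoderConfig,
    channels: ChannelFlags = ALL_CHANNELS,
) -> EncodedBatch:
    return RecordCache(records, vocab, config, channels).batch(range(len(records)))


# -- forward pieces ----------------------------------------------------------


def _dropout(x: T.Tensor, p: float, rng: Optional[np.random.Generator]) -> T.Tensor:
    if p <= 0.0 or rng is None:
        return x
    mask = (rng.random(x.shape) >= p).astype(np.float32) / np.float32(1.0 - p)
    return x * T.Tensor(mask)


def transformer_layer_batched(
    x: T.Tensor,
    params: ModelParameters,
    layer: int,
    mask_add: np.ndarray,
    dropout_p: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    return_attn: bool = False,
):
    """Post-norm transformer block on (B, L, d) with an additive attention
    mask (0 allowed, large-negative forbidden), broadcastable to (B, H, L, L)."""
    p = params.tensors
    cfg = params.config
    B, L, d = x.shape
    H, dh = cfg.n_heads, cfg.d // cfg.n_heads

    def heads(t):
        return t.reshape(B, L, H, dh).transpose(0, 2, 1, 3)  # (B,H,L,dh)

    q = heads(x @ p[f"L{layer}.Wq"] + p[f"L{layer}.bq"])
    k = heads(x @ p[f"L{layer}.Wk"] + p[f"L{layer}.bk"])
    v = heads(x @ p[f"L{layer}.Wv"] + p[f"L{layer}.bv"])
    scores = (q @ k.transpose(0, 1, 3, 2)) * np.float32(1.0 / np.sqrt(dh))
    scores = scores + T.Tensor(mask_add.astype(np.float32))
    attn = T.softmax(scores, axis=-1)
    ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, d)
    ctx = _dropout(ctx @ p[f"L{layer}.Wo"] + p[f"L{layer}.bo"], dropout_p, rng)
    h = T.layernorm(
        x + ctx, p[f"L{layer}.ln1_g"], p[f"L{layer}.ln1_b"], cfg.layernorm_eps
    )
    ffn = (h @ p[f"L{layer}.W1"] + p[f"L{layer}.b1"]).relu() @ p[f"L{layer}.W2"] + p[
        f"L{layer}.b2"
    ]
    out = T.layernorm(
        h + _dropout(ffn, dropout_p, rng),
        p[f"L{layer}.ln2_g"],
        p[f"L{layer}.ln2_b"],
        cfg.layernorm_eps,
    )
    if return_attn:
        return out, attn.data
    return out


def transformer_layer(
    inputs: np.ndarray,
    params: ModelParameters,
    mask: Optional[np.ndarray] = None,
    layer: int = 0,
    return_attn: bool = False,
):
    """Single-sequence convenience: inputs (L, d), boolean mask (L, L) with
    True = may attend.  Rows forbidding every position are rejected."""
    inputs = np.asarray(inputs, dtype=np.float32)
    L = inputs.shape[0]
    if mask is None:
        mask = np.ones((L, L), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any(axis=1).all():
        raise ValueError("attention mask forbids every position for some row")
    add = np.where(mask, np.float32(0.0), _NEG)[None, None]
    out = transformer_layer_batched(
        T.Tensor(inputs[None]), params, layer, add, return_attn=return_attn
    )
    if return_attn:
        out, attn = out
        return out.data[0], attn[0]
    return out.data[0]


def _visit_vectors_flat(
    batch: EncodedBatch, params: ModelParameters, channels: ChannelFlags
) -> T.Tensor:
    """Max-pooled embedding of every real visit → (M, d)."""
    p = params.tensors
    M = batch.type_idx.shape[0]
    e = None
    if channels.code_channels() and len(batch.flat_code_idx):
        rows = T.embedding(p["E_code"], batch.flat_code_idx)
        e = T.segment_max(rows, batch.code_seg, M)
    if channels.util:
        t = T.embedding(p["E_type"], batch.type_idx)
        e = t if e is None else T.maximum(e, t)
    if channels.date:
        g = T.embedding(p["E_date"], batch.bucket_idx)
        e = g if e is None else T.maximum(e, g)
    if e is None:
        raise ValueError("no channels enabled")
    return e


def _attention_mask(visit_mask: np.ndarray, mode: str, include_visits: bool) -> np.ndarray:
    B, Tm = visit_mask.shape
    L = 1 + (Tm if include_visits else 0)
    allowed = np.ones((B, 1, L, L), dtype=bool)
    if include_visits:
        key_ok = np.concatenate([np.ones((B, 1), dtype=bool), visit_mask], axis=1)
        allowed &= key_ok[:, None, None, :]
    if mode == CAUSAL:
        allowed &= np.tril(np.ones((L, L), dtype=bool))[None, None]
    elif mode != BIDIRECTIONAL:
        raise ValueError(f"unknown attention mode {mode!r}")
    return np.where(allowed, np.float32(0.0), _NEG)


def encode_batch(
    records,
    params: ModelParameters,
    mode: str = BIDIRECTIONAL,
    channels: ChannelFlags = ALL_CHANNELS,
    include_visits: bool = True,
    dropout_p: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    batch: Optional[EncodedBatch] = None,
):
    """Differentiable forward pass over a list of records.

    Returns ``(pe, visit_states, batch)`` where ``pe`` is (B, d) and
    ``visit_states`` is (B, Tmax, d) aligned with ``batch.visit_mask``
    (``None`` when ``include_visits`` is False).
    """
    if batch is None:
        batch = prepare_batch(records, _require_vocab(params), params.config, channels)
    p = params.tensors
    B = batch.demo.shape[0]
    demo_tok = (T.Tensor(batch.demo) @ p["W_demo"]).reshape(B, 1, -1)
    if include_visits:
        e = _visit_vectors_flat(batch, params, channels)
        grid = T.scatter_rows(e, (batch.visit_b, batch.visit_t), batch.visit_mask.shape)
        x = T.concat([demo_tok, grid], axis=1)
    else:
        x = demo_tok
    mask_add = _attention_mask(batch.visit_mask, mode, include_visits)
    for l in range(params.config.n_layers):
        x = transformer_layer_batched(x, params, l, mask_add, dropout_p, rng)
    pe = x[:, 0, :]
    states = x[:, 1:, :] if include_visits else None
    return pe, states, batch


def _require_vocab(params: ModelParameters) -> CodeVocabulary:
    if params.vocab is None:
        raise ValueError(
            "ModelParameters has no bound vocabulary; pass a prepared batch or "
            "call bind_vocab first"
        )
    return params.vocab


def bind_vocab(params: ModelParameters, vocab: CodeVocabulary) -> ModelParameters:
    if vocab.total_size != params.vocab_size:
        raise ValueError(
            f"vocabulary size {vocab.total_size} does not match model "
            f"({params.vocab_size})"
        )
    params.vocab = vocab
    return params


def encode_patient(
    record: PatientRecord,
    params: ModelParameters,
    mode: str = BIDIRECTIONAL,
    channels: ChannelFlags = ALL_CHANNELS,
) -> PatientEncoding:
    if not record.visits:
        raise ValueError("record has no visits")
    pe, states, batch = encode_batch([record], params, mode=mode, channels=channels)
    t = int(batch.visit_mask[0].sum())
    return PatientEncoding(pe=pe.data[0].copy(), visit_states=states.data[0, :t].copy())


def embed_visit(
    visit: Visit,
    params: ModelParameters,
    vocab: CodeVocabulary,
    channels: ChannelFlags = ALL_CHANNELS,
    prev_date: Optional[int] = None,
) -> np.ndarray:
    """One visit's max-pooled embedding (the e_t of the sequence input)."""
    rec = _SingleVisitRecord(visit)
    batch = prepare_batch([rec], vocab, params.config, channels)
    if prev_date is not None:
        batch.bucket_idx[0] = date_bucket(max(visit.service_date - prev_date, 0))
    return _visit_vectors_flat(batch, params, channels).data[0].copy()


class _SingleVisitRecord:
    """Lightweight stand-in with the attributes prepare_batch touches."""

    def __init__(self, visit: Visit):
        self.visits = [visit]
        self.gender = "U"
        self.birth_year = 2000

    @property
    def age_at_first_visit(self):
        return 0.0


# -- checkpoints --------------------------------------------------------------


@dataclass
class Checkpoint:
    """A trained body plus the vocabulary/grouper it was trained against.
    Fine-tuning refuses checkpoints whose fingerprints do not match the
    cohort's vocabulary."""

    params: ModelParameters
    vocab: CodeVocabulary
    grouper: CategoryGrouper

    def __post_init__(self):
        bind_vocab(self.params, self.vocab)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(
            directory / "params.npz",
            **{k: v.data for k, v in self.params.tensors.items()},
        )
        self.vocab.to_tsv(directory / "vocab.tsv")
        self.grouper.to_tsv(directory / "grouper.tsv")
        meta = {
            "encoder": asdict(self.params.config),
            "vocab_size": self.params.vocab_size,
            "n_categories": self.params.n_categories,
            "vocab_fingerprint": self.vocab.fingerprint(),
            "grouper_fingerprint": self.grouper.fingerprint(),
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "Checkpoint":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        vocab = CodeVocabulary.from_tsv(directory / "vocab.tsv")
        grouper = CategoryGrouper.from_tsv(directory / "grouper.tsv")
        if vocab.fingerprint() != meta["vocab_fingerprint"]:
            raise ValueError("vocabulary fingerprint mismatch in checkpoint")
        if grouper.fingerprint() != meta["grouper_fingerprint"]:
            raise ValueError("grouper fingerprint mismatch in checkpoint")
        params = ModelParameters(
            EncoderConfig(**meta["encoder"]), meta["vocab_size"], meta["n_categories"]
        )
        with np.load(directory / "params.npz") as npz:
            params.tensors = {
                k: T.Tensor(npz[k].copy(), requires_grad=True) for k in npz.files
            }
        return cls(params=params, vocab=vocab, grouper=grouper)
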