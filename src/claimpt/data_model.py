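"""Domain types for longitudinal claims data, file formats, vocabularies,
code→category groupers, and case/control cohort selection.

A patient is a date-ordered sequence of visits; each visit carries a service
date, a visit type (inpatient ``IP``, outpatient ``OP``, pharmacy ``RX``) and
per-channel sets of medical codes (diagnoses ``DIAG``, procedures ``PROC``,
medications ``DRUG``).  On disk a corpus is line-delimited JSON, one patient
per line; groupers and vocabularies are 3-column TSV.
"""

from __future__ import annotations

import datetime as _dt
import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

CHANNELS = ("DIAG", "PROC", "DRUG")
VISIT_TYPES = ("IP", "OP", "RX")
GENDERS = ("M", "F", "U")
OOV_TOKEN = "<OOV>"

_EPOCH = _dt.date(1970, 1, 1).toordinal()
_JSON_KEYS = {"DIAG": "dx", "PROC": "px", "DRUG": "rx"}


def date_to_days(iso: str) -> int:
    """ISO-8601 day string → days since 1970-01-01."""
    return _dt.date.fromisoformat(iso).toordinal() - _EPOCH


def days_to_date(days: int) -> str:
    return _dt.date.fromordinal(days + _EPOCH).isoformat()


class ClaimsFormatError(ValueError):
    """Raised for malformed claims files; message names line/record."""


@dataclass(frozen=True)
class MedicalCode:
    code: str
    channel: str

    def __post_init__(self):
        if not self.code:
            raise ValueError("medical code must be non-empty")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")


@dataclass
class Visit:
    service_date: int  # days since 1970-01-01
    visit_type: str
    codes: dict  # channel -> frozenset[str]

    def __post_init__(self):
        if self.visit_type not in VISIT_TYPES:
            raise ValueError(f"unknown visit_type {self.visit_type!r}")
        self.codes = {ch: frozenset(self.codes.get(ch, ())) for ch in CHANNELS}
        if not any(self.codes.values()):
            raise ValueError("visit must carry at least one code")


@dataclass
class PatientRecord:
    patient_id: str
    gender: str
    birth_year: int
    visits: list
    label: Optional[int] = None

    def __post_init__(self):
        if self.gender not in GENDERS:
            raise ValueError(f"unknown gender {self.gender!r}")
        if not self.visits:
            raise ValueError(f"patient {self.patient_id!r} has no visits")
        self.visits = sorted(self.visits, key=lambda v: v.service_date)

    @property
    def age_at_first_visit(self) -> float:
        first = _dt.date.fromordinal(self.visits[0].service_date + _EPOCH)
        return first.year - self.birth_year + (first.timetuple().tm_yday - 1) / 365.25


@dataclass
class LabeledExample:
    record: PatientRecord
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


# -- claims file I/O --------------------------------------------------------


def _visit_to_json(v: Visit) -> dict:
    d = {"date": days_to_date(v.service_date), "type": v.visit_type}
    for ch in CHANNELS:
        d[_JSON_KEYS[ch]] = sorted(v.codes[ch])
    return d


def _record_to_json(r: PatientRecord) -> dict:
    d = {
        "patient_id": r.patient_id,
        "gender": r.gender,
        "birth_year": r.birth_year,
        "visits": [_visit_to_json(v) for v in r.visits],
    }
    if r.label is not None:
        d["label"] = int(r.label)
    return d


def write_claims(records: Iterable[PatientRecord], path) -> None:
    """Write records as JSON-lines; ``read_claims`` round-trips the output."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps(_record_to_json(r), ensure_ascii=False) + "\n")


def read_claims(path) -> list:
    """Parse a JSON-lines claims file into PatientRecords (visits re-sorted)."""
    records = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as e:
                raise ClaimsFormatError(f"line {lineno}: invalid JSON ({e})") from e
            for key in ("patient_id", "gender", "birth_year", "visits"):
                if key not in obj:
                    raise ClaimsFormatError(f"line {lineno}: missing field {key!r}")
            visits = []
            for j, v in enumerate(obj["visits"]):
                for key in ("date", "type"):
                    if key not in v:
                        raise ClaimsFormatError(
                            f"line {lineno}: visit {j}: missing field {key!r}"
                        )
                if v["type"] not in VISIT_TYPES:
                    raise ClaimsFormatError(
                        f"line {lineno}: visit {j}: unknown visit type {v['type']!r}"
                    )
                visits.append(
                    Visit(
                        service_date=date_to_days(v["date"]),
                        visit_type=v["type"],
                        codes={ch: v.get(_JSON_KEYS[ch], []) for ch in CHANNELS},
                    )
                )
            try:
                rec = PatientRecord(
                    patient_id=obj["patient_id"],
                    gender=obj["gender"],
                    birth_year=int(obj["birth_year"]),
                    visits=visits,
                    label=obj.get("label"),
                )
            except ValueError as e:
                raise ClaimsFormatError(f"line {lineno}: {e}") from e
            records.append(rec)
    return records


# -- vocabulary -------------------------------------------------------------


@dataclass
class CodeVocabulary:
    """Dense per-channel code index; frequency-descending, ties broken by
    code string, with a reserved out-of-vocabulary slot at each channel's end.

    A single *global* index (per-channel blocks concatenated in CHANNELS
    order) is exposed for heads that score the full code space at once.
    """

    index: dict = field(default_factory=dict)  # channel -> {code: idx}

    @property
    def channels(self):
        return CHANNELS

    def n_codes(self, channel: str) -> int:
        """Vocabulary size of a channel excluding the OOV slot."""
        return len(self.index[channel])

    def size(self, channel: str) -> int:
        """Vocabulary size of a channel including the OOV slot."""
        return len(self.index[channel]) + 1

    def oov_index(self, channel: str) -> int:
        return len(self.index[channel])

    @property
    def total_size(self) -> int:
        return sum(self.size(ch) for ch in CHANNELS)

    def channel_offset(self, channel: str) -> int:
        off = 0
        for ch in CHANNELS:
            if ch == channel:
                return off
            off += self.size(ch)
        raise KeyError(channel)

    def code_index(self, channel: str, code: str) -> int:
        return self.index[channel].get(code, self.oov_index(channel))

    def global_index(self, channel: str, code: str) -> int:
        return self.channel_offset(channel) + self.code_index(channel, code)

    def global_labels(self) -> list:
        """Human-readable label per global index (``channel:code``)."""
        out = []
        for ch in CHANNELS:
            inv = sorted(self.index[ch].items(), key=lambda kv: kv[1])
            out.extend(f"{ch}:{c}" for c, _ in inv)
            out.append(f"{ch}:{OOV_TOKEN}")
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("channel\tcode\tindex\n")
            for ch in CHANNELS:
                for code, idx in sorted(self.index[ch].items(), key=lambda kv: kv[1]):
                    fh.write(f"{ch}\t{code}\t{idx}\n")
                fh.write(f"{ch}\t{OOV_TOKEN}\t{self.oov_index(ch)}\n")

    @classmethod
    def from_tsv(cls, path) -> "CodeVocabulary":
        index = {ch: {} for ch in CHANNELS}
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("channel\tcode\tindex"):
                raise ClaimsFormatError("vocabulary TSV missing header")
            for line in fh:
                ch, code, idx = line.rstrip("\n").split("\t")
                if code != OOV_TOKEN:
                    index[ch][code] = int(idx)
        return cls(index=index)

    def fingerprint(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for ch in CHANNELS:
            for code, idx in sorted(self.index[ch].items(), key=lambda kv: kv[1]):
                h.update(f"{ch}\t{code}\t{idx}\n".encode())
        return h.hexdigest()


def build_vocabulary(records: Sequence[PatientRecord], min_count: int = 5) -> CodeVocabulary:
    """Index every (channel, code) whose corpus frequency ≥ min_count.

    Index order is frequency-descending with lexicographic tie-break so the
    assignment is a pure function of the corpus; filtered codes fall back to
    each channel's OOV slot.
    """
    if min_count < 0:
        raise ValueError("min_count must be non-negative")
    counts = {ch: Counter() for ch in CHANNELS}
    for r in records:
        for v in r.visits:
            for ch in CHANNELS:
                counts[ch].update(v.codes[ch])
    index = {}
    threshold = max(min_count, 1)
    for ch in CHANNELS:
        kept = [(c, n) for c, n in counts[ch].items() if n >= threshold]
        kept.sort(key=lambda cn: (-cn[1], cn[0]))
        index[ch] = {c: i for i, (c, _) in enumerate(kept)}
    return CodeVocabulary(index=index)


# -- category grouper -------------------------------------------------------


@dataclass
class CategoryGrouper:
    """Many-to-one (channel, code) → category map, e.g. CCS for diagnoses and
    procedures and NDC drug classes for medications.  Codes absent from the
    table map to a per-channel OOV category.
    """

    mapping: dict = field(default_factory=dict)  # channel -> {code: category}

    def map(self, channel: str, code: str) -> str:
        return self.mapping[channel].get(code, OOV_TOKEN)

    def categories(self, channel: str) -> list:
        """Dense category list for a channel: sorted unique categories + OOV."""
        return sorted(set(self.mapping[channel].values())) + [OOV_TOKEN]

    def n_categories(self, channel: str) -> int:
        return len(self.categories(channel))

    @property
    def total_categories(self) -> int:
        return sum(self.n_categories(ch) for ch in CHANNELS)

    def category_offset(self, channel: str) -> int:
        off = 0
        for ch in CHANNELS:
            if ch == channel:
                return off
            off += self.n_categories(ch)
        raise KeyError(channel)

    def global_category_index(self, channel: str, code: str) -> int:
        cats = self.categories(channel)
        return self.category_offset(channel) + cats.index(self.map(channel, code))

    def category_index_table(self) -> dict:
        """Precomputed (channel → {code: global category index}) for hot loops."""
        table = {}
        for ch in CHANNELS:
            cats = {c: i for i, c in enumerate(self.categories(ch))}
            off = self.category_offset(ch)
            table[ch] = {
                code: off + cats[cat] for code, cat in self.mapping[ch].items()
            }
            table[ch][OOV_TOKEN] = off + cats[OOV_TOKEN]
        return table

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("channel\tcode\tcategory\n")
            for ch in CHANNELS:
                for code in sorted(self.mapping[ch]):
                    fh.write(f"{ch}\t{code}\t{self.mapping[ch][code]}\n")

    @classmethod
    def from_tsv(cls, path) -> "CategoryGrouper":
        mapping = {ch: {} for ch in CHANNELS}
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("channel\tcode\tcategory"):
                raise ClaimsFormatError("grouper TSV missing header")
            for line in fh:
                ch, code, cat = line.rstrip("\n").split("\t")
                mapping[ch][code] = cat
        return cls(mapping=mapping)

    def fingerprint(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for ch in CHANNELS:
            for code in sorted(self.mapping[ch]):
                h.update(f"{ch}\t{code}\t{self.mapping[ch][code]}\n".encode())
        return h.hexdigest()


def map_code_to_category(grouper: CategoryGrouper, channel: str, code: str) -> str:
    return grouper.map(channel, code)


# -- cohort selection -------------------------------------------------------


@dataclass
class Cohort:
    """Result of case/control selection: shuffled labeled examples plus
    bookkeeping on how many cases were dropped for having no pre-event
    history."""

    examples: list
    n_cases: int
    n_controls: int
    n_dropped_cases: int

    def __iter__(self):
        return iter(self.examples)

    def __len__(self):
        return len(self.examples)


def select_cohort(
    records: Sequence[PatientRecord],
    case_predicate: Callable[[Visit], bool],
    control_ratio: float = 2.0,
    seed: int = 0,
) -> Cohort:
    """Build a case/control cohort around a visit-level index event.

    Cases (label 1) keep only visits *strictly before* their first event
    visit; cases whose first visit is the event are dropped (no usable
    history) and counted.  Controls (label 0) are non-case patients sampled
    uniformly without replacement at ``control_ratio`` per case, keeping all
    visits.  The output order is shuffled by ``seed``.
    """
    if control_ratio <= 0:
        raise ValueError("control_ratio must be positive")
    cases, dropped, control_pool = [], 0, []
    for r in records:
        event_idx = next(
            (i for i, v in enumerate(r.visits) if case_predicate(v)), None
        )
        if event_idx is None:
            control_pool.append(r)
        elif event_idx == 0:
            dropped += 1
        else:
            truncated = PatientRecord(
                patient_id=r.patient_id,
                gender=r.gender,
                birth_year=r.birth_year,
                visits=list(r.visits[:event_idx]),
            )
            cases.append(LabeledExample(truncated, 1))
    if not cases:
        raise ValueError(
            f"no usable cases: {dropped} case(s) dropped for lacking pre-event history"
        )
    n_controls = int(round(control_ratio * len(cases)))
    if n_controls > len(control_pool):
        raise ValueError(
            f"need {n_controls} controls but only {len(control_pool)} available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(control_pool), size=n_controls, replace=False)
    controls = [LabeledExample(control_pool[i], 0) for i in chosen]
    examples = cases + controls
    rng.shuffle(examples)
    return Cohort(
        examples=examples,
        n_cases=len(cases),
        n_controls=n_controls,
        n_dropped_cases=dropped,
    )


def cohort_from_labels(
    records: Sequence[PatientRecord],
    n_cases: int,
    control_ratio: float = 2.0,
    seed: int = 0,
) -> Cohort:
    """Case/control sampling for patient-level binary labels (e.g. the
    simulator's latent-risk labels): draw ``n_cases`` positives and
    ``control_ratio`` as many negatives, shuffled by ``seed``."""
    pos = [r for r in records if r.label == 1]
    neg = [r for r in records if r.label == 0]
    n_controls = int(round(control_ratio * n_cases))
    if n_cases > len(pos) or n_controls > len(neg):
        raise ValueError(
            f"requested {n_cases}+{n_controls}, corpus has {len(pos)}+{len(neg)}"
        )
    rng = np.random.default_rng(seed)
    cases = [LabeledExample(pos[i], 1) for i in rng.choice(len(pos), n_cases, replace=False)]
    controls = [
        LabeledExample(neg[i], 0) for i in rng.choice(len(neg), n_controls, replace=False)
    ]
    examples = cases + controls
    rng.shuffle(examples)
    return Cohort(examples, n_cases, n_controls, 0)
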