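"""Synthetic longitudinal claims generator.

Emulates the statistical structure a claims sequence model has to exploit:
a per-patient latent health-state Markov chain drives visit types and
state-conditional, long-tailed code emissions (so codes co-occur and the
next visit is partially predictable); inter-visit gaps are log-normal
(uneven spacing); every code belongs to exactly one category via a
deterministic grouper (contiguous blocks of the frequency-ranked code
list); and a binary downstream label depends on the fraction of time spent
in a designated high-risk state.  Calibration targets follow a large
pediatric Medicaid population: ~10.4 visits per patient, ~2.8 codes per
visit, 49.8% male, ages 0–18.

The generator is deterministic under a fixed seed (byte-identical output
files) and exposes its parameter tables through :class:`GroundTruth` so
tests can compute information-theoretic quantities exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .data_model import (
    CHANNELS,
    CategoryGrouper,
    PatientRecord,
    Visit,
    date_to_days,
)

_CODE_PREFIX = {"DIAG": "D", "PROC": "P", "DRUG": "R"}

# channel mix per visit type: rows IP, OP, RX; cols DIAG, PROC, DRUG
_CHANNEL_MIX = {
    "IP": (0.60, 0.30, 0.10),
    "OP": (0.60, 0.25, 0.15),
    "RX": (0.10, 0.00, 0.90),
}


@dataclass
class SimulationConfig:
    n_patients: int = 5000
    n_codes: dict = field(
        default_factory=lambda: {"DIAG": 300, "PROC": 120, "DRUG": 80}
    )
    n_categories: dict = field(
        default_factory=lambda: {"DIAG": 15, "PROC": 6, "DRUG": 4}
    )
    n_latent_states: int = 4
    mean_visits_per_patient: float = 10.4
    mean_codes_per_visit: float = 2.8
    gap_log_mean: float = math.log(30.0)  # log-days; median gap 30 days
    gap_log_sd: float = 1.0
    stay_prob: float = 0.7  # Markov self-transition
    state_mix: float = 0.7  # weight of the state-preferred code block
    zipf_exponent: float = 1.0  # long-tail exponent of the base code law
    label_effect: float = 6.0  # latent-state → label log-odds strength
    male_fraction: float = 0.498
    max_age: int = 18  # pediatric population: age at first visit ~ U[0, 18]
    first_date_range: tuple = ("2013-01-01", "2014-12-31")
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0 or self.n_latent_states <= 0:
            raise ValueError("counts must be positive")
        for ch in CHANNELS:
            if self.n_codes[ch] <= 0:
                raise ValueError(f"n_codes[{ch}] must be positive")
            if self.n_categories[ch] > self.n_codes[ch]:
                raise ValueError(
                    f"n_categories[{ch}]={self.n_categories[ch]} exceeds "
                    f"n_codes[{ch}]={self.n_codes[ch]}"
                )
        if not (0.0 <= self.stay_prob <= 1.0 and 0.0 <= self.state_mix <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.mean_visits_per_patient < 1 or self.mean_codes_per_visit < 1:
            raise ValueError("per-unit means must be at least 1")


@dataclass
class GenParams:
    """The generative parameter tables: everything the sampler draws from."""

    code_probs: dict  # channel -> (n_states, V_ch) rows summing to 1
    transition: np.ndarray  # (n_states, n_states)
    type_probs: np.ndarray  # (n_states, 3) over VISIT_TYPES order IP,OP,RX

    @classmethod
    def build(cls, config: SimulationConfig, rng: np.random.Generator) -> "GenParams":
        S = config.n_latent_states
        code_probs = {}
        for ch in CHANNELS:
            V = config.n_codes[ch]
            base = 1.0 / (np.arange(V) + 1.0) ** config.zipf_exponent
            base /= base.sum()
            pref = rng.integers(S, size=V)  # random state-preferred partition
            probs = np.empty((S, V))
            for s in range(S):
                block = base * (pref == s)
                if block.sum() == 0:  # tiny vocabularies: fall back to base law
                    block = base
                probs[s] = config.state_mix * block / block.sum() + (
                    1 - config.state_mix
                ) * base
            code_probs[ch] = probs / probs.sum(axis=1, keepdims=True)
        off = (1.0 - config.stay_prob) / max(S - 1, 1)
        transition = np.full((S, S), off)
        np.fill_diagonal(transition, config.stay_prob if S > 1 else 1.0)
        type_probs = np.empty((S, 3))
        for s in range(S):
            ip = 0.05 + 0.30 * (s / max(S - 1, 1))  # sicker states → more inpatient
            type_probs[s] = (ip, 1.0 - ip - 0.30, 0.30)
        return cls(code_probs=code_probs, transition=transition, type_probs=type_probs)


@dataclass
class GroundTruth:
    states: list  # per patient: np.ndarray of latent states, one per visit
    label_prob: np.ndarray  # per patient: P(y=1 | latent chain)
    params: GenParams
    config: SimulationConfig


class SimulatedCorpus(NamedTuple):
    records: list
    grouper: CategoryGrouper
    ground_truth: GroundTruth


def _build_grouper(config: SimulationConfig) -> CategoryGrouper:
    """Deterministic grouper: contiguous category blocks over the
    frequency-ranked code list of each channel."""
    mapping = {}
    for ch in CHANNELS:
        V, K = config.n_codes[ch], config.n_categories[ch]
        p = _CODE_PREFIX[ch]
        mapping[ch] = {
            f"{p}{rank:04d}": f"{p}CAT{rank * K // V:02d}" for rank in range(V)
        }
    return CategoryGrouper(mapping=mapping)


def _code_name(channel: str, rank: int) -> str:
    return f"{_CODE_PREFIX[channel]}{rank:04d}"


def _sample_corpus(
    config: SimulationConfig, params: GenParams, rng: np.random.Generator
) -> tuple:
    S = config.n_latent_states
    first_lo = date_to_days(config.first_date_range[0])
    first_hi = date_to_days(config.first_date_range[1])
    high_risk = S - 1
    records, all_states, label_probs = [], [], []
    pad = len(str(max(config.n_patients - 1, 1)))
    for i in range(config.n_patients):
        gender = "M" if rng.random() < config.male_fraction else "F"
        n_visits = 1 + rng.poisson(config.mean_visits_per_patient - 1.0)
        states = np.empty(n_visits, dtype=np.int64)
        states[0] = rng.integers(S)
        for t in range(1, n_visits):
            states[t] = rng.choice(S, p=params.transition[states[t - 1]])
        date = int(rng.integers(first_lo, first_hi + 1))
        first_year = 1970 + date // 365  # close enough for a birth-year draw
        birth_year = first_year - int(rng.integers(0, config.max_age + 1))
        visits = []
        for t in range(n_visits):
            if t > 0:
                gap = max(1, int(round(rng.lognormal(config.gap_log_mean, config.gap_log_sd))))
                date += gap
            vtype = ("IP", "OP", "RX")[rng.choice(3, p=params.type_probs[states[t]])]
            n_tokens = 1 + rng.poisson(config.mean_codes_per_visit - 1.0)
            ch_counts = rng.multinomial(n_tokens, _CHANNEL_MIX[vtype])
            codes = {}
            for ch, k in zip(CHANNELS, ch_counts):
                if k == 0:
                    continue
                V = config.n_codes[ch]
                k = min(k, V)
                picks = rng.choice(V, size=k, replace=False, p=params.code_probs[ch][states[t]])
                codes[ch] = {_code_name(ch, int(r)) for r in picks}
            visits.append(Visit(service_date=date, visit_type=vtype, codes=codes))
        f_high = float(np.mean(states == high_risk))
        p_label = 1.0 / (1.0 + math.exp(-config.label_effect * (f_high - 1.0 / S)))
        label = int(rng.random() < p_label)
        records.append(
            PatientRecord(
                patient_id=f"P{i:0{pad}d}",
                gender=gender,
                birth_year=birth_year,
                visits=visits,
                label=label,
            )
        )
        all_states.append(states)
        label_probs.append(p_label)
    return records, all_states, np.asarray(label_probs)


def simulate_population(config: SimulationConfig) -> SimulatedCorpus:
    """Draw a full corpus; same config (and seed) → byte-identical output."""
    config.validate()
    param_rng = np.random.default_rng([config.seed, 0x70A])
    patient_rng = np.random.default_rng([config.seed, 0x9A7])
    params = GenParams.build(config, param_rng)
    records, states, label_probs = _sample_corpus(config, params, patient_rng)
    gt = GroundTruth(states=states, label_prob=label_probs, params=params, config=config)
    return SimulatedCorpus(records, _build_grouper(config), gt)


def make_transfer_pair(
    config_a: SimulationConfig, config_b: SimulationConfig, overlap: float
) -> tuple:
    """Two corpora whose state-conditional code distributions share an
    ``overlap`` fraction: 1.0 → corpus B is drawn from A's tables (same
    institution, held-out years); 0.0 → B's tables are independently drawn
    (a foreign institution); intermediate values mix the two linearly.

    Both corpora share the code space and grouper (``n_codes`` and
    ``n_categories`` must match) so a model pre-trained on A can be applied
    to B.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError(f"overlap must be in [0, 1], got {overlap}")
    config_a.validate()
    config_b.validate()
    if config_a.n_codes != config_b.n_codes or config_a.n_categories != config_b.n_categories:
        raise ValueError("transfer pair must share the code/category space")
    bundle_a = simulate_population(config_a)
    params_b_own = GenParams.build(
        config_b, np.random.default_rng([config_b.seed, 0x70A])
    )
    mixed = {
        ch: overlap * bundle_a.ground_truth.params.code_probs[ch]
        + (1.0 - overlap) * params_b_own.code_probs[ch]
        for ch in CHANNELS
    }
    params_b = GenParams(
        code_probs=mixed,
        transition=params_b_own.transition,
        type_probs=params_b_own.type_probs,
    )
    rng_b = np.random.default_rng([config_b.seed, 0x9A7])
    records_b, states_b, probs_b = _sample_corpus(config_b, params_b, rng_b)
    gt_b = GroundTruth(states=states_b, label_prob=probs_b, params=params_b, config=config_b)
    bundle_b = SimulatedCorpus(records_b, _build_grouper(config_b), gt_b)
    return bundle_a, bundle_b


# -- diagnostics ------------------------------------------------------------


def corpus_summary(records) -> dict:
    """Exact marginal statistics of a corpus (the calibration readout)."""
    if not records:
        raise ValueError("corpus is empty")
    n_visits = sum(len(r.visits) for r in records)
    n_codes = sum(
        sum(len(v.codes[ch]) for ch in CHANNELS) for r in records for v in r.visits
    )
    unique = {
        ch: len({c for r in records for v in r.visits for c in v.codes[ch]})
        for ch in CHANNELS
    }
    return {
        "n_patients": len(records),
        "n_visits": n_visits,
        "mean_visits_per_patient": n_visits / len(records),
        "mean_codes_per_visit": n_codes / n_visits,
        "unique_codes": unique,
        "unique_codes_total": sum(unique.values()),
        "male_pct": 100.0 * sum(r.gender == "M" for r in records) / len(records),
        "mean_age": float(np.mean([r.age_at_first_visit for r in records])),
    }


def state_code_tv_distance(params_a: GenParams, params_b: GenParams) -> float:
    """Mean total-variation distance between the two parameter sets'
    state-conditional code distributions (over states and channels)."""
    tvs = [
        0.5 * np.abs(params_a.code_probs[ch] - params_b.code_probs[ch]).sum(axis=1).mean()
        for ch in CHANNELS
    ]
    return float(np.mean(tvs))


def state_code_mutual_information(params: GenParams, channel: str) -> float:
    """I(state; code) in nats under a uniform state distribution, computed
    exactly from the emission tables."""
    p = params.code_probs[channel]
    marginal = p.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p > 0, np.log(p / marginal), 0.0)
    return float((p * ratio).mean(axis=0).sum())


def write_ground_truth(gt: GroundTruth, path) -> None:
    """Per-patient sidecar JSONL: latent states and label probability."""
    import json

    with open(path, "w", encoding="utf-8") as fh:
        for i, (states, p) in enumerate(zip(gt.states, gt.label_prob)):
            fh.write(
                json.dumps(
                    {"index": i, "states": [int(s) for s in states], "label_prob": float(p)}
                )
                + "\n"
            )
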