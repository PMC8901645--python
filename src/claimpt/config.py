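"""Layered configuration, deterministic seed fan-out, and run manifests."""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional


class ConfigError(ValueError):
    pass


def resolve_config(defaults, file_overrides: Optional[dict] = None, cli_overrides: Optional[dict] = None):
    """Merge defaults < file < CLI into a new config instance.

    ``defaults`` is a dataclass instance; override keys must name its fields
    (unknown keys are rejected with the valid key list) and values are
    coerced to the field's type where unambiguous.
    """
    if not dataclasses.is_dataclass(defaults):
        raise TypeError("defaults must be a dataclass instance")
    fields = {f.name: f for f in dataclasses.fields(defaults)}
    merged = {}
    for layer in (file_overrides or {}, cli_overrides or {}):
        for key, value in layer.items():
            if key not in fields:
                raise ConfigError(
                    f"unknown config key {key!r}; valid keys: "
                    + ", ".join(sorted(fields))
                )
            merged[key] = _coerce(key, value, getattr(defaults, key))
    return dataclasses.replace(defaults, **merged)


def _coerce(key, value, current):
    if current is None or value is None:
        return value
    want = type(current)
    if isinstance(value, want):
        return value
    if want is float and isinstance(value, int):
        return float(value)
    if want is int and isinstance(value, float) and value == int(value):
        return int(value)
    if want is bool and isinstance(value, str):
        low = value.lower()
        if low in ("true", "1", "yes"):
            return True
        if low in ("false", "0", "no"):
            return False
    if isinstance(value, str):
        try:
            return want(value)
        except (TypeError, ValueError):
            pass
    if want in (dict, tuple, list) and isinstance(value, (dict, tuple, list)):
        return want(value)
    raise ConfigError(
        f"config key {key!r} expects {want.__name__}, got {type(value).__name__}"
    )


SEED_COMPONENTS = (
    "simulator",
    "split",
    "init",
    "shuffle",
    "cohort",
    "pretrain",
    "finetune",
)


def seed_everything(master_seed: int) -> dict:
    """Counter-based fan-out of one master seed into per-component seeds.

    Each component's seed is a pure function of (master seed, component
    name), so adding components never shifts existing ones.  Seeds are kept
    below 2³¹.
    """
    out = {}
    for name in SEED_COMPONENTS:
        digest = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
        out[name] = int.from_bytes(digest[:4], "big") % (2**31)
    return out


def hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-run a pipeline bit-for-bit: the resolved
    config, content hashes of the inputs, the code version, and the seed
    fan-out.  Written before training begins."""

    command: str
    config: dict
    input_hashes: dict
    master_seed: int
    seed_map: dict = field(default_factory=dict)
    code_version: str = ""
    started: str = ""
    finished: str = ""

    def __post_init__(self):
        if not self.seed_map:
            self.seed_map = seed_everything(self.master_seed)
        if not self.code_version:
            from . import __version__

            self.code_version = __version__
        if not self.started:
            self.started = _dt.datetime.now(_dt.timezone.utc).isoformat()

    def finish(self) -> "RunManifest":
        self.finished = _dt.datetime.now(_dt.timezone.utc).isoformat()
        return self

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))

    def verify_inputs(self) -> None:
        for name, recorded in self.input_hashes.items():
            if hash_file(name) != recorded:
                raise ConfigError(f"input file {name} changed since the manifest")
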