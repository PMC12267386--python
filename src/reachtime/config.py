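"""YAML run configuration.

One document drives a whole simulated study: protocol constants, cohort
population hyperparameters, cohort size, and the master seed.  Every
default reproduces the published protocol (260/2000 ms displays, 1000–2000
and 3000–4500 ms intervals, 0.6/0.75/0.9 m/s staged speeds, 30°/35° grid
angles, 0.028 m base radius, 0.10 m cubes, 100/1000/600 ms cutoffs).
CLI flags override file values; all randomness flows from ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping, Union

import yaml

from .protocol import ProtocolConfig
from .simulant import CohortParams, ExGauss, ParticipantParams


class ConfigError(ValueError):
    """Unusable run configuration."""


@dataclass(frozen=True)
class RunConfig:
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    population: CohortParams = field(default_factory=CohortParams)
    n_participants: int = 48
    seed: int = 0
    out_dir: str = "cohort"

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ConfigError("n_participants must be at least 2")


def _build(cls, data: Mapping[str, Any], **extra):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(data)
    for key in ("phase1_isi_ms", "reach_isi_ms", "dynamic_speeds"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    kwargs.update(extra)
    return cls(**kwargs)


def _participant_params(data: Mapping[str, Any]) -> ParticipantParams:
    data = dict(data)
    if "exgauss" in data:
        data["exgauss"] = {
            k: ExGauss(*v) if not isinstance(v, ExGauss) else v
            for k, v in data["exgauss"].items()
        }
    return _build(ParticipantParams, data)


def load_run_config(source: Union[str, Path, Mapping[str, Any], None]) -> RunConfig:
    """Load a RunConfig from a YAML path, a mapping, or None (defaults)."""
    if source is None:
        return RunConfig()
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text()) or {}
    else:
        raw = dict(source)
    if not isinstance(raw, Mapping):
        raise ConfigError("run config must be a mapping")

    pop_raw = dict(raw.get("population", {}))
    if "base" in pop_raw:
        pop_raw["base"] = _participant_params(pop_raw["base"])
    return RunConfig(
        protocol=_build(ProtocolConfig, raw.get("protocol", {})),
        population=_build(CohortParams, pop_raw),
        n_participants=int(raw.get("n_participants", 48)),
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "cohort")),
    )


def run_config_digest(cfg: RunConfig) -> str:
    """Short stable hash of a config, for logging reproducibility."""
    import hashlib
    import json

    def enc(obj):
        if hasattr(obj, "__dataclass_fields__"):
            return {f.name: enc(getattr(obj, f.name)) for f in fields(obj)}
        if isinstance(obj, Mapping):
            return {k: enc(v) for k, v in sorted(obj.items())}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj

    return hashlib.sha256(
        json.dumps(enc(cfg), sort_keys=True).encode()
    ).hexdigest()[:12]
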