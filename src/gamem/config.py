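"""Run configuration: schema-validated YAML with full defaulting.

Unknown keys are rejected; every field left to its default is logged so a
run directory always contains one fully-resolved configuration from which
the run can be replayed bit-for-bit.
"""

from __future__ import annotations

import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .bistable import G_MAINTENANCE, G_PAIRING, G_US_ALONE, TRIAL_DURATION

log = logging.getLogger("gamem")

__all__ = ["RunConfig", "load_config", "resolve_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class BistableConfig(_Strict):
    beta: float = Field(1.8, gt=0)
    K: float = Field(1.0, gt=0)
    n: int = Field(4, ge=2)
    delta: float = Field(1.0, gt=0)
    sigma: float = Field(0.18, ge=0)
    g_levels: dict[str, float] = Field(
        default_factory=lambda: {
            "maintenance": G_MAINTENANCE,
            "pairing": G_PAIRING,
            "us_alone": G_US_ALONE,
        }
    )

    @model_validator(mode="after")
    def _check_levels(self):
        missing = {"maintenance", "pairing", "us_alone"} - set(self.g_levels)
        if missing:
            raise ValueError(f"g_levels missing keys: {sorted(missing)}")
        return self


class MarkovConfig(_Strict):
    p: float = Field(0.35, ge=0, le=1)
    q: float = Field(0.15, ge=0, le=1)
    f: float = Field(0.2, gt=0, lt=1)
    N: int = Field(100, ge=1)


class PopulationConfig(_Strict):
    Z: int | str = "inf"

    @model_validator(mode="after")
    def _check_z(self):
        if isinstance(self.Z, str) and self.Z != "inf":
            raise ValueError('Z must be a positive integer or "inf"')
        if isinstance(self.Z, int) and self.Z < 1:
            raise ValueError("Z must be >= 1")
        return self


class ProtocolConfig(_Strict):
    n_patterns: int = Field(3, ge=1)
    trial_duration: float = Field(TRIAL_DURATION, gt=0)
    gap: float = Field(TRIAL_DURATION, ge=0)


class RunConfig(_Strict):
    bistable: BistableConfig = BistableConfig()
    markov: MarkovConfig = MarkovConfig()
    population: PopulationConfig = PopulationConfig()
    protocol: ProtocolConfig = ProtocolConfig()
    seed: int = 0
    out_dir: str = "gamem-out"
    dt: float = Field(0.02, gt=0)
    t_end: float = Field(100.0, gt=0)
    verbosity: str = "info"

    def bistable_params(self):
        from .bistable import BistableParams

        b = self.bistable
        return BistableParams(b.beta, b.K, b.n, b.delta, b.sigma)

    def markov_params(self):
        from .markov import MarkovParams

        m = self.markov
        return MarkovParams(m.p, m.q, m.f, m.N)


def resolve_config(data: dict | None) -> RunConfig:
    """Validate raw config data, logging the provenance of defaults."""
    data = data or {}
    cfg = RunConfig(**data)
    given = set(data)
    for name in RunConfig.model_fields:
        origin = "file" if name in given else "default"
        log.debug("config field %-12s <- %s", name, origin)
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    return resolve_config(raw)


def write_resolved(cfg: RunConfig, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "resolved-config.yaml"
    path.write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))
    return path
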