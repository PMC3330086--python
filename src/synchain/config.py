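"""Run configuration: schema, YAML/JSON serialization, and hashing.

A run configuration bundles the model parameters, the dendritic modulation,
the stimulation/observation protocol and the analysis thresholds.  Every
field has a default taken from the active fixture, so a config file only
needs to list overrides.  A short SHA-256 hash of the canonical JSON form is
embedded in all output files for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fixtures import fixture
from .model import DendriticModulation, ModelParams

__all__ = ["ProtocolConfig", "AnalysisConfig", "RunConfig", "load_config"]


@dataclass(frozen=True)
class ProtocolConfig:
    """Stimulation and observation protocol (times in membrane time constants)."""

    t_eq: float = 50.0  # equilibration before any observation
    pre_window: float = 50.0  # background observation before the stimulus
    post_window: float = 20.0  # background observation after the chain window
    horizon: int = 50  # chain steps followed after initiation
    g0: int = 100  # stimulated group size
    n_transit_init: int | None = None  # initial spikes in transit (None: N*p_conn)
    stim_prefix: bool = False  # stimulate neurons 0..g0-1 instead of a random subset


@dataclass(frozen=True)
class AnalysisConfig:
    """Classification thresholds."""

    f_max: float = 0.1  # background pulse fraction of N above which background is unstable
    K_min: int = 20  # chain groups that must beat the background for persistence


@dataclass
class RunConfig:
    model: ModelParams
    modulation: DendriticModulation
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0

    @classmethod
    def from_fixture(cls, name: str = "nonlinear_ref", **overrides) -> "RunConfig":
        params, mod = fixture(name)
        return cls(model=params, modulation=mod, **overrides)

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "modulation": self.modulation.to_dict(),
            "protocol": dataclasses.asdict(self.protocol),
            "analysis": dataclasses.asdict(self.analysis),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {"model", "modulation", "protocol", "analysis", "seed", "fixture"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base = cls.from_fixture(d.get("fixture", "nonlinear_ref"))
        model = {**base.model.to_dict(), **d.get("model", {})}
        modulation = {**base.modulation.to_dict(), **d.get("modulation", {})}
        try:
            return cls(
                model=ModelParams.from_dict(model),
                modulation=DendriticModulation.from_dict(modulation),
                protocol=ProtocolConfig(**d.get("protocol", {})),
                analysis=AnalysisConfig(**d.get("analysis", {})),
                seed=int(d.get("seed", 0)),
            )
        except (TypeError, ValueError) as e:
            raise ValueError(f"invalid configuration: {e}") from e

    def save(self, path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=True)
        )
        path.write_text(text, encoding="utf-8")

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load a YAML or JSON run configuration (missing keys take fixture defaults)."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return RunConfig.from_dict(raw)
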