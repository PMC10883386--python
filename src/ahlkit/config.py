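"""Pipeline configuration: every screening/mining threshold in one place.

The config round-trips losslessly through YAML; command-line flags override
file values, and the effective config is echoed into every run report.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .msms import ScreenParams

__all__ = ["MiningParams", "ClusterParams", "PipelineConfig"]


@dataclass(frozen=True)
class MiningParams:
    hmm_evalue_threshold: float = 1e-5
    blast_evalue_threshold: float = 0.01
    blast_query_length: int | None = None

    def __post_init__(self) -> None:
        if self.hmm_evalue_threshold <= 0 or self.blast_evalue_threshold <= 0:
            raise ValueError("E-value thresholds must be positive")


@dataclass(frozen=True)
class ClusterParams:
    k: int = 4
    n_init: int = 10

    def __post_init__(self) -> None:
        if self.k < 1 or self.n_init < 1:
            raise ValueError("k and n_init must be >= 1")


@dataclass(frozen=True)
class PipelineConfig:
    screen: ScreenParams = field(default_factory=ScreenParams)
    mining: MiningParams = field(default_factory=MiningParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    seed: int = 0
    verbosity: int = 1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["screen"]["confirm_set"] = list(d["screen"]["confirm_set"])
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        screen_kw = dict(data.get("screen", {}))
        if "confirm_set" in screen_kw:
            screen_kw["confirm_set"] = tuple(screen_kw["confirm_set"])
        return cls(
            screen=ScreenParams(**screen_kw),
            mining=MiningParams(**data.get("mining", {})),
            cluster=ClusterParams(**data.get("cluster", {})),
            seed=int(data.get("seed", 0)),
            verbosity=int(data.get("verbosity", 1)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def override(self, **kwargs) -> "PipelineConfig":
        """Return a copy with top-level fields replaced (None = keep)."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates)
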