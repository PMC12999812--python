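"""Pipeline configuration: every tunable threshold with its default.

Loadable from a YAML file with CLI override precedence; weight-sum
invariants are enforced at load time so a malformed config fails before any
stage runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # preprocessing
    min_count: float = 15
    min_fraction: float = 0.75
    vst_method: str = "parametric"
    # network
    powers: list[int] = field(
        default_factory=lambda: list(range(1, 11)) + list(range(12, 51, 2))
    )
    r2_threshold: float = 0.8
    # module detection
    min_module_size: int = 30
    deep_split: int = 2
    merge_cut_height: float = 0.25
    # enrichment
    alpha: float = 0.05
    min_set_size: int = 5
    max_set_size: int = 2000
    # drug prioritization
    score_weights: list[float] = field(default_factory=lambda: [0.4, 0.3, 0.3])
    priority_weights: list[float] = field(default_factory=lambda: [0.7, 0.3])
    top_n: int = 20
    sim_threshold: float = 0.8
    # export
    edge_quantile: float = 0.75
    # reproducibility
    seed: int = 1234

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.score_weights), 1.0):
            raise ValueError(f"score weights must sum to 1, got {self.score_weights}")
        if not np.isclose(sum(self.priority_weights), 1.0):
            raise ValueError(f"priority weights must sum to 1, got {self.priority_weights}")
        if not 0 <= self.deep_split <= 4:
            raise ValueError("deep_split must be in 0..4")
        if not 0 < self.edge_quantile < 1:
            raise ValueError("edge_quantile must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
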