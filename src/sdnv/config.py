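"""Pipeline configuration: a single validated JSON document.

Defaults mirror the analysis settings the pipeline targets: selection
threshold alpha = 0.05 (robustness set {0.10, 0.05, 0.01}), 40-s windows
(robustness {30, 40, 50} s), TR = 2 s, 1,000 permutations, strict 95%
important-node threshold, 50-mm framewise-displacement radius.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path


@dataclass
class PipelineConfig:
    alpha: float = 0.05
    window_length_seconds: float = 40.0
    tr_seconds: float = 2.0
    mode: str = "simple"                  # simple | partial
    scope: str = "whole-brain"            # whole-brain | network
    total_rule: str = "pooled"            # pooled | averaged
    include_self: bool = False
    n_perm: int = 1000
    important_node_threshold: float = 0.95
    fd_radius_mm: float = 50.0
    rotation_unit: str = "degrees"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.window_length_seconds <= 0:
            raise ValueError("window_length_seconds must be positive")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.mode not in ("simple", "partial"):
            raise ValueError(f"mode must be 'simple' or 'partial', got {self.mode!r}")
        if self.scope not in ("whole-brain", "network"):
            raise ValueError(f"scope must be 'whole-brain' or 'network', got {self.scope!r}")
        if self.total_rule not in ("pooled", "averaged"):
            raise ValueError(f"total_rule must be 'pooled' or 'averaged', got {self.total_rule!r}")
        if self.n_perm < 0:
            raise ValueError("n_perm must be nonnegative")
        if not 0 < self.important_node_threshold < 1:
            raise ValueError("important_node_threshold must lie in (0, 1)")
        if self.fd_radius_mm <= 0:
            raise ValueError("fd_radius_mm must be positive")
        if self.rotation_unit not in ("degrees", "radians"):
            raise ValueError(f"rotation_unit must be 'degrees' or 'radians'")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
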