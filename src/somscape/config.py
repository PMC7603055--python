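"""Run configuration: one serializable object holds every tunable.

All randomness in a run flows from the single ``seed``. The config is
written as YAML next to every output so any artifact can be reproduced
from its directory alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    grid_rows: int = 60
    grid_cols: int = 60
    epochs: int = 20
    seed: int = 1
    k_segments: int = 32
    spot_quantile: float = 0.98
    pt_k: int = 15
    pt_components: int = 10
    velocity_quantile: float = 0.05
    pseudocount: float = 1.0
    min_cells: int = 0
    root_cell_type: str = "stem"

    def __post_init__(self) -> None:
        if self.grid_rows * self.grid_cols < 4:
            raise ValueError("grid too small")
        if self.epochs < 1 or self.k_segments < 1:
            raise ValueError("epochs and k_segments must be positive")
        if not 0 < self.spot_quantile < 1:
            raise ValueError("spot_quantile must lie in (0, 1)")
        if not 0 < self.velocity_quantile <= 0.5:
            raise ValueError("velocity_quantile must lie in (0, 0.5]")

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
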