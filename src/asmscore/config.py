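"""Run configuration: one object holding every policy knob of a run.

Defaults are the documented pipeline defaults; a YAML config file can set
any subset, and CLI flags override the file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class RunConfig:
    metric_matrix: Optional[str] = None
    dataset_sheet: Optional[str] = None
    registry: Optional[str] = None
    out_dir: str = "asmscore_out"
    seed: int = 0
    verbosity: int = 1

    missing_policy: str = "zero"          # "zero" | "omit"
    degenerate_value: float = 0.5         # score for constant metric vectors
    cluster_metric: str = "euclidean"
    cluster_method: str = "average"
    full_length_threshold: float = 0.9
    full_length_strict: bool = True
    exn50_fraction: float = 0.9
    max_evalue: Optional[float] = 1e-20   # CLI alignment pre-filter

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def merged(self, **overrides) -> "RunConfig":
        """Return a copy with non-None overrides applied (CLI wins)."""
        data = asdict(self)
        for k, v in overrides.items():
            if v is not None:
                data[k] = v
        return RunConfig(**data)
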