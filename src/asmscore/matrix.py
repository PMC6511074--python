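"""Long-format metric matrix containers.

The interchange format throughout the package is a tidy long table with the
columns ``dataset, assembler, metric, value`` — one row per evaluated cell.
Missing cells are either absent rows or NaN values; both mean the same thing.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional

import numpy as np
import pandas as pd

COLUMNS = ("dataset", "assembler", "metric", "value")


class RawMetricMatrix:
    """Raw evaluation scores over datasets x assemblers x metrics.

    Wraps a long-format :class:`pandas.DataFrame`. Values may be negative
    (e.g. log-likelihood based scores) or fractional; a NaN value marks a
    missing cell.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"metric matrix missing columns: {missing}")
        df = data.loc[:, list(COLUMNS)].copy()
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        dup = df.duplicated(subset=["dataset", "assembler", "metric"])
        if dup.any():
            first = df.loc[dup.idxmax(), ["dataset", "assembler", "metric"]]
            raise ValueError(
                "duplicate (dataset, assembler, metric) triple: "
                f"({first['dataset']}, {first['assembler']}, {first['metric']})"
            )
        self.data = df.reset_index(drop=True)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str, float]]
    ) -> "RawMetricMatrix":
        return cls(pd.DataFrame(list(records), columns=list(COLUMNS)))

    @property
    def datasets(self) -> list[str]:
        return list(dict.fromkeys(self.data["dataset"]))

    @property
    def assemblers(self) -> list[str]:
        return list(dict.fromkeys(self.data["assembler"]))

    @property
    def metrics(self) -> list[str]:
        return list(dict.fromkeys(self.data["metric"]))

    def pivot(self, dataset: str) -> pd.DataFrame:
        """Wide view for one dataset: metrics (rows) x assemblers (columns)."""
        sub = self.data[self.data["dataset"] == dataset]
        if sub.empty:
            raise KeyError(f"unknown dataset id: {dataset}")
        wide = sub.pivot(index="metric", columns="assembler", values="value")
        # keep first-appearance order on both axes
        midx = [m for m in self.metrics if m in set(wide.index)]
        aidx = [a for a in self.assemblers if a in set(wide.columns)]
        return wide.loc[midx, aidx]

    def get(self, dataset: str, assembler: str, metric: str) -> float:
        sub = self.data[
            (self.data["dataset"] == dataset)
            & (self.data["assembler"] == assembler)
            & (self.data["metric"] == metric)
        ]
        if sub.empty:
            return math.nan
        return float(sub["value"].iloc[0])

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        return (
            f"{type(self).__name__}({len(self.datasets)} datasets x "
            f"{len(self.assemblers)} assemblers x {len(self.metrics)} metrics)"
        )


class NormalizedMatrix(RawMetricMatrix):
    """(0,1)-normalized scores; every non-missing value lies in [0, 1]."""

    def __init__(self, data: pd.DataFrame):
        super().__init__(data)
        vals = self.data["value"].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("normalized values must lie in [0, 1]")
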