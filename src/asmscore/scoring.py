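"""Normalization and metric-score aggregation for assembler comparison.

The comparison works on one latent question — which assembler produced the
better transcriptome — observed through many heterogeneous metrics whose
scales and orientations differ. For each (dataset, metric) pair the raw
scores of all assemblers form a vector v; it is min-max normalized

    n_k = (v_k - min v) / (max v - min v)

so the worst assembler on that metric scores 0 and the best 1 (penalty
metrics are inverted: n_k = (max v - v_k) / (max v - min v)). This is
equivalent to a z-score transformation followed by rescaling into [0, 1],
since both are affine maps fixed by the sample extremes.

Per dataset and assembler the normalized scores are summed into the metric
score MS (maximum = number of applicable metrics); per assembler the MS
values are summed over datasets into the overall metric score OMS, with
datasets in a replicate group contributing their mean MS once.

:class:`AssemblyScorer` runs the whole chain as a scikit-learn style
estimator; the module-level functions expose the individual steps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, TransformerMixin

from .matrix import COLUMNS, NormalizedMatrix, RawMetricMatrix
from .registry import (
    Applicability,
    DatasetInfo,
    Direction,
    MetricDefinition,
    applicable_metrics,
    builtin_registry,
)

logger = logging.getLogger(__name__)

ArrayLike = Union[Sequence[float], np.ndarray]


class NonNormalizableError(ValueError):
    """Raised when a metric vector has no non-missing value to normalize."""


def normalize_vector(
    values: ArrayLike,
    direction: Union[Direction, str] = Direction.HIGHER_BETTER,
    degenerate_value: float = 0.5,
) -> np.ndarray:
    """Min-max normalize one raw-score vector into [0, 1].

    Parameters
    ----------
    values
        Raw scores of all assemblers for one (dataset, metric) pair; NaN
        marks a missing cell and is passed through (and excluded from the
        min/max).
    direction
        ``higher_better`` maps the maximum to 1; ``lower_better`` inverts,
        mapping the minimum to 1.
    degenerate_value
        Output for every assembler when all non-missing raw values are
        equal (min == max leaves the map undefined); the default 0.5 is a
        neutral contribution. Set to 0.0 to score a non-discriminating
        metric as worthless.

    Raises
    ------
    NonNormalizableError
        If every input value is missing.
    """
    direction = Direction(direction)
    v = np.asarray(values, dtype=float)
    mask = np.isfinite(v)
    if not mask.any():
        raise NonNormalizableError("all values missing: cannot normalize")
    vmin = v[mask].min()
    vmax = v[mask].max()
    out = np.full_like(v, np.nan)
    if vmax == vmin:
        out[mask] = degenerate_value
        return out
    if direction is Direction.HIGHER_BETTER:
        out[mask] = (v[mask] - vmin) / (vmax - vmin)
    else:
        out[mask] = (vmax - v[mask]) / (vmax - vmin)
    return out


def _direction_map(registry: Sequence[MetricDefinition]) -> dict[str, Direction]:
    return {m.metric_id: m.direction for m in registry}


def normalize_matrix(
    raw: RawMetricMatrix,
    registry: Optional[Sequence[MetricDefinition]] = None,
    datasets: Optional[Sequence[DatasetInfo]] = None,
    degenerate_value: float = 0.5,
) -> NormalizedMatrix:
    """Normalize every (dataset, metric) vector of a raw matrix.

    Each vector is normalized independently across assemblers with the
    direction the registry assigns to its metric. Metrics not applicable to
    a dataset's layout are dropped from the output; degenerate (constant)
    vectors are mapped to ``degenerate_value`` with a logged warning.
    """
    registry = list(registry) if registry is not None else builtin_registry()
    directions = _direction_map(registry)
    ds_by_id = {d.dataset_id: d for d in datasets} if datasets is not None else {}

    if not raw.assemblers:
        raise ValueError("matrix contains no assemblers")

    rows = []
    for did in raw.datasets:
        ds = ds_by_id.get(did)
        allowed = (
            applicable_metrics(ds, registry) if ds is not None else set(directions)
        )
        wide = raw.pivot(did)
        for mid in wide.index:
            if mid not in allowed:
                continue
            vec = wide.loc[mid].to_numpy(dtype=float)
            if not np.isfinite(vec).any():
                continue
            finite = vec[np.isfinite(vec)]
            if finite.size and finite.min() == finite.max():
                logger.warning(
                    "degenerate metric %s in dataset %s (all values equal): "
                    "normalized to %.2f",
                    mid,
                    did,
                    degenerate_value,
                )
            try:
                norm = normalize_vector(
                    vec, directions.get(mid, Direction.HIGHER_BETTER), degenerate_value
                )
            except NonNormalizableError as exc:
                raise NonNormalizableError(
                    f"metric {mid} in dataset {did}: {exc}"
                ) from exc
            for aid, n in zip(wide.columns, norm):
                rows.append((did, aid, mid, n))
    return NormalizedMatrix(pd.DataFrame(rows, columns=list(COLUMNS)))


def metric_score(
    norm: NormalizedMatrix,
    dataset_id: str,
    assembler_id: str,
    missing_policy: str = "zero",
) -> float:
    """Metric score MS: sum of normalized scores for one (dataset, assembler).

    ``missing_policy`` controls cells missing for this assembler while
    present for others: ``"zero"`` (default) scores them 0 — an assembler
    for which a metric could not be computed is treated as worst — while
    ``"omit"`` leaves them out of the sum.
    """
    if missing_policy not in ("zero", "omit"):
        raise ValueError(f"unknown missing-cell policy: {missing_policy!r}")
    wide = norm.pivot(dataset_id)
    if assembler_id not in wide.columns:
        raise KeyError(f"unknown assembler id: {assembler_id}")
    col = wide[assembler_id]
    # rows where every assembler is NaN never entered normalization; a NaN
    # here means this assembler alone lacks the value
    present_any = wide.notna().any(axis=1)
    col = col[present_any]
    if missing_policy == "zero":
        return float(col.fillna(0.0).sum())
    return float(col.dropna().sum())


def overall_metric_score(
    ms: pd.DataFrame,
    datasets: Optional[Sequence[DatasetInfo]] = None,
) -> pd.Series:
    """Overall metric score OMS per assembler.

    ``ms`` is the dataset x assembler MS table. Ungrouped datasets add
    their MS directly; datasets sharing a ``replicate_group`` add the
    arithmetic mean of their MS values once, so repeated near-identical
    experiments are not over-weighted. Groups missing some members use the
    available ones.
    """
    ds_by_id = {d.dataset_id: d for d in datasets} if datasets is not None else {}
    groups: dict[str, list[str]] = {}
    singles: list[str] = []
    for did in ms.index:
        g = ds_by_id.get(did).replicate_group if did in ds_by_id else None
        if g is None:
            singles.append(did)
        else:
            groups.setdefault(g, []).append(did)

    oms = ms.loc[singles].sum(axis=0) if singles else pd.Series(0.0, index=ms.columns)
    for members in groups.values():
        oms = oms + ms.loc[members].mean(axis=0)
    oms.name = "OMS"
    return oms


def rank_assemblers(oms: Mapping[str, float]) -> list[str]:
    """Order assemblers by descending OMS; ties broken by assembler id."""
    if not len(oms):
        raise ValueError("empty score map")
    items = list(dict(oms).items())
    return [a for a, _ in sorted(items, key=lambda kv: (-kv[1], kv[0]))]


def cluster_profiles(
    ms: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "average",
) -> tuple[np.ndarray, list[str]]:
    """Hierarchically cluster assemblers by their MS profile across datasets.

    Returns the SciPy linkage matrix and the assembler leaf order. Display
    aid only — clustering never feeds back into MS or OMS.
    """
    if ms.shape[1] < 2:
        raise ValueError("clustering needs at least 2 assemblers")
    profiles = ms.T.to_numpy(dtype=float)  # assemblers x datasets
    dist = pdist(profiles, metric=metric)
    link = hierarchy.linkage(dist, method=method)
    leaves = hierarchy.leaves_list(link)
    return link, [ms.columns[i] for i in leaves]


@dataclass
class ScoreTable:
    """MS per (dataset, assembler), applicable-metric counts, and OMS."""

    ms: pd.DataFrame
    max_possible: pd.Series
    oms: pd.Series
    ranking: list[str] = field(default_factory=list)


class MetricNormalizer(TransformerMixin, BaseEstimator):
    """Per-(dataset, metric) min-max normalizer with metric orientation.

    A transformer over long-format metric tables: ``fit`` learns the
    per-(dataset, metric) extremes across assemblers, ``transform`` maps raw
    values into [0, 1] with penalty metrics inverted. Fitting and
    transforming the same table is the standard use; transforming new
    assemblers against frozen extremes is possible but clips outside [0, 1].

    Parameters
    ----------
    registry : sequence of MetricDefinition, optional
        Metric panel with directions; defaults to the built-in 20-metric
        registry.
    datasets : sequence of DatasetInfo, optional
        Dataset sheet used for layout-based applicability; if omitted every
        metric is assumed applicable.
    degenerate_value : float, default 0.5
        Output for constant metric vectors (see :func:`normalize_vector`).
    """

    def __init__(self, registry=None, datasets=None, degenerate_value: float = 0.5):
        self.registry = registry
        self.datasets = datasets
        self.degenerate_value = degenerate_value

    def _as_matrix(self, X) -> RawMetricMatrix:
        if isinstance(X, RawMetricMatrix):
            return X
        return RawMetricMatrix(pd.DataFrame(X, columns=list(COLUMNS)))

    def fit(self, X, y=None):
        raw = self._as_matrix(X)
        registry = (
            list(self.registry) if self.registry is not None else builtin_registry()
        )
        self.registry_ = registry
        self.directions_ = _direction_map(registry)
        extremes: dict[tuple[str, str], tuple[float, float]] = {}
        for did in raw.datasets:
            wide = raw.pivot(did)
            for mid in wide.index:
                vec = wide.loc[mid].to_numpy(dtype=float)
                finite = vec[np.isfinite(vec)]
                if finite.size:
                    extremes[(did, mid)] = (float(finite.min()), float(finite.max()))
        self.extremes_ = extremes
        self.n_features_in_ = 4
        return self

    def transform(self, X) -> NormalizedMatrix:
        if not hasattr(self, "extremes_"):
            raise RuntimeError("MetricNormalizer is not fitted")
        raw = self._as_matrix(X)
        ds = self.datasets
        ds_by_id = {d.dataset_id: d for d in ds} if ds is not None else {}
        rows = []
        for did in raw.datasets:
            info = ds_by_id.get(did)
            allowed = (
                applicable_metrics(info, self.registry_)
                if info is not None
                else set(self.directions_)
            )
            wide = raw.pivot(did)
            for mid in wide.index:
                if mid not in allowed or (did, mid) not in self.extremes_:
                    continue
                vmin, vmax = self.extremes_[(did, mid)]
                vec = wide.loc[mid].to_numpy(dtype=float)
                out = np.full_like(vec, np.nan)
                mask = np.isfinite(vec)
                if vmax == vmin:
                    out[mask] = self.degenerate_value
                else:
                    direction = self.directions_.get(mid, Direction.HIGHER_BETTER)
                    if direction is Direction.HIGHER_BETTER:
                        out[mask] = (vec[mask] - vmin) / (vmax - vmin)
                    else:
                        out[mask] = (vmax - vec[mask]) / (vmax - vmin)
                    out = np.clip(out, 0.0, 1.0)
                for aid, n in zip(wide.columns, out):
                    rows.append((did, aid, mid, n))
        return NormalizedMatrix(pd.DataFrame(rows, columns=list(COLUMNS)))


class AssemblyScorer(BaseEstimator):
    """Full scoring chain: normalize, sum to MS, aggregate to OMS, rank.

    ``fit`` consumes a long-format raw metric table (or
    :class:`RawMetricMatrix`) and exposes the results as fitted attributes.

    Parameters
    ----------
    registry : sequence of MetricDefinition, optional
        Metric directions and applicability; defaults to the built-in panel.
    datasets : sequence of DatasetInfo, optional
        Layouts (18-vs-20 applicable metrics) and replicate groups.
    missing_policy : {"zero", "omit"}, default "zero"
        Treatment of cells missing for one assembler but present for others.
    degenerate_value : float, default 0.5
        Normalized output for constant metric vectors.
    cluster_metric, cluster_method : str
        Distance and linkage for the display clustering of MS profiles.

    Attributes
    ----------
    normalized_ : NormalizedMatrix
    ms_ : DataFrame, datasets x assemblers
    max_possible_ : Series, applicable-metric count per dataset
    oms_ : Series, overall metric score per assembler
    ranking_ : list of assembler ids, best first
    linkage_ : ndarray, SciPy linkage of MS profiles (None if <2 assemblers)
    leaf_order_ : list of assembler ids in dendrogram order
    """

    def __init__(
        self,
        registry=None,
        datasets=None,
        missing_policy: str = "zero",
        degenerate_value: float = 0.5,
        cluster_metric: str = "euclidean",
        cluster_method: str = "average",
    ):
        self.registry = registry
        self.datasets = datasets
        self.missing_policy = missing_policy
        self.degenerate_value = degenerate_value
        self.cluster_metric = cluster_metric
        self.cluster_method = cluster_method

    def fit(self, X, y=None):
        raw = (
            X
            if isinstance(X, RawMetricMatrix)
            else RawMetricMatrix(pd.DataFrame(X, columns=list(COLUMNS)))
        )
        registry = (
            list(self.registry) if self.registry is not None else builtin_registry()
        )
        datasets = list(self.datasets) if self.datasets is not None else None

        norm = normalize_matrix(raw, registry, datasets, self.degenerate_value)
        self.normalized_ = norm

        ds_by_id = {d.dataset_id: d for d in datasets} if datasets else {}
        ms = pd.DataFrame(
            index=pd.Index(norm.datasets, name="dataset"),
            columns=pd.Index(norm.assemblers, name="assembler"),
            dtype=float,
        )
        for did in norm.datasets:
            for aid in norm.assemblers:
                ms.loc[did, aid] = metric_score(norm, did, aid, self.missing_policy)
        self.ms_ = ms

        self.max_possible_ = pd.Series(
            {
                did: len(applicable_metrics(ds_by_id[did], registry))
                if did in ds_by_id
                else len(registry)
                for did in norm.datasets
            },
            name="max_possible",
        )
        self.oms_ = overall_metric_score(ms, datasets)
        self.ranking_ = rank_assemblers(self.oms_)
        if ms.shape[1] >= 2:
            self.linkage_, self.leaf_order_ = cluster_profiles(
                ms, self.cluster_metric, self.cluster_method
            )
        else:
            self.linkage_, self.leaf_order_ = None, list(ms.columns)
        return self

    def score_table(self) -> ScoreTable:
        if not hasattr(self, "ms_"):
            raise RuntimeError("AssemblyScorer is not fitted")
        return ScoreTable(
            ms=self.ms_.copy(),
            max_possible=self.max_possible_.copy(),
            oms=self.oms_.copy(),
            ranking=list(self.ranking_),
        )
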