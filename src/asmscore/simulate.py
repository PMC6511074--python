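"""Synthetic benchmark inputs with known ground truth.

Every generator here is a pure function of its parameters and a seed, and
returns the planted truth alongside the data, so each pipeline stage can be
tested end to end without any external evaluator runs: metric matrices with
a planted assembler-quality ordering observed through noisy metrics of mixed
orientation, transcript sets whose expression-weighted N50 is known by
construction, alignment tables with designed protein coverage, and
assemblies with planted length and ambiguous-base composition.

Seeding: a single master seed is expanded with ``numpy``'s ``SeedSequence``
into independent per-component streams (one child per dataset/metric or per
protein), so generated parts are decoupled but jointly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._table2 import (
    TABLE2_ASSEMBLERS,
    TABLE2_DATASET_ID,
    TABLE2_MS,
    TABLE2_NORMALIZED,
    TABLE2_RAW,
)
from .derived import AlignmentSegment, AssemblyStats, TranscriptExpressionRecord, n50
from .matrix import COLUMNS, RawMetricMatrix
from .registry import (
    DatasetInfo,
    Direction,
    Layout,
    MetricDefinition,
    builtin_registry,
)


@dataclass
class PlantedDesign:
    """Design of a synthetic benchmark with a latent quality ordering.

    ``quality`` is a strictly decreasing vector, one value per assembler:
    assembler 0 is planted best. Observed metric values are a per-metric
    monotone transform of quality (decreasing for penalty metrics) plus
    Gaussian noise with standard deviation ``noise_sd`` on the quality
    scale. Defaults mirror a realistic benchmark: 9 datasets, 10
    assemblers, a quality range of width 1 and noise_sd 0.1 (clearly
    separated tools with occasional metric-level rank flips).
    """

    n_datasets: int = 9
    n_assemblers: int = 10
    quality: Optional[Sequence[float]] = None
    noise_sd: float = 0.1
    seed: int = 0
    replicate_groups: dict[str, list[str]] = field(default_factory=dict)
    registry: Optional[Sequence[MetricDefinition]] = None
    single_end_datasets: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.quality is None:
            self.quality = np.linspace(1.0, 0.0, self.n_assemblers)
        q = np.asarray(self.quality, dtype=float)
        if q.size != self.n_assemblers:
            raise ValueError("quality vector length must equal n_assemblers")
        if not (np.diff(q) < 0).all():
            raise ValueError("quality vector must be strictly decreasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def assembler_ids(self) -> list[str]:
        return [f"asm{k:02d}" for k in range(self.n_assemblers)]

    @property
    def dataset_ids(self) -> list[str]:
        return [f"ds{i:02d}" for i in range(self.n_datasets)]

    def dataset_sheet(self) -> list[DatasetInfo]:
        group_of = {
            did: g for g, members in self.replicate_groups.items() for did in members
        }
        return [
            DatasetInfo(
                dataset_id=did,
                layout=Layout.SINGLE_END
                if did in self.single_end_datasets
                else Layout.PAIRED_END,
                replicate_group=group_of.get(did),
            )
            for did in self.dataset_ids
        ]


def gen_metric_matrix(
    design: PlantedDesign,
) -> tuple[RawMetricMatrix, list[str]]:
    """Simulate a raw metric matrix under a planted quality ordering.

    Each (dataset, metric) vector is ``offset + scale * (q + noise)`` for
    quality metrics and ``offset - scale * (q + noise)`` for penalty
    metrics, with per-(dataset, metric) offset and scale drawn from a
    dedicated random stream; so at noise_sd 0 every metric ranks the
    assemblers exactly by planted quality. Returns the matrix and the
    planted order (assembler ids, best first).
    """
    registry = (
        list(design.registry) if design.registry is not None else builtin_registry()
    )
    q = np.asarray(design.quality, dtype=float)
    aids = design.assembler_ids
    dids = design.dataset_ids
    streams = np.random.SeedSequence(design.seed).spawn(len(dids) * len(registry))

    rows = []
    for i, did in enumerate(dids):
        for j, mdef in enumerate(registry):
            rng = np.random.default_rng(streams[i * len(registry) + j])
            offset = rng.uniform(-50.0, 50.0)
            scale = rng.uniform(0.5, 20.0)
            noise = rng.normal(0.0, design.noise_sd, size=q.size)
            sign = 1.0 if mdef.direction is Direction.HIGHER_BETTER else -1.0
            vals = offset + sign * scale * (q + noise)
            for aid, v in zip(aids, vals):
                rows.append((did, aid, mdef.metric_id, float(v)))
    matrix = RawMetricMatrix(pd.DataFrame(rows, columns=list(COLUMNS)))
    planted_order = [aids[k] for k in np.argsort(-q, kind="stable")]
    return matrix, planted_order


def gen_transcripts(
    n: int = 100,
    expression_skew: float = 0.91,
    seed: int = 0,
    dominant_length: int = 500,
    background_length_range: tuple[int, int] = (1000, 10000),
) -> tuple[list[TranscriptExpressionRecord], int]:
    """Simulate a transcript expression table with known Ex90N50.

    Two regimes, chosen by ``expression_skew`` (the expression share of a
    single dominant transcript):

    * skew > 0.9 — a single short, highly expressed transcript carries
      ``expression_skew`` of the total; the remaining transcripts share the
      rest uniformly and are drawn longer. The 90%-expression prefix is the
      dominant transcript alone, so the expected Ex90N50 equals
      ``dominant_length`` by construction.
    * skew <= 1/n — expression is uniform and all transcripts share one
      length; the expected Ex90N50 is that common length for any fraction.

    Intermediate skews are rejected (no closed-form ground truth).
    Returns (records, expected_ex90n50).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    if expression_skew > 0.9 and n >= 2:
        lo, hi = background_length_range
        records = [
            TranscriptExpressionRecord("t0000", dominant_length, expression_skew)
        ]
        rest = (1.0 - expression_skew) / (n - 1)
        for i in range(1, n):
            records.append(
                TranscriptExpressionRecord(
                    f"t{i:04d}", int(rng.integers(lo, hi + 1)), rest
                )
            )
        return records, dominant_length
    if expression_skew <= 1.0 / n or n == 1:
        length = dominant_length
        records = [
            TranscriptExpressionRecord(f"t{i:04d}", length, 1.0 / n) for i in range(n)
        ]
        return records, length
    raise ValueError(
        "expression_skew must be > 0.9 (dominant design) or <= 1/n (uniform)"
    )


def gen_alignments(
    n_proteins: int = 100,
    coverage_profile: Optional[Sequence[float]] = None,
    seed: int = 0,
    n_segments: int = 2,
    length_range: tuple[int, int] = (100, 1000),
) -> tuple[list[AlignmentSegment], dict[str, int], int]:
    """Simulate a tabular alignment set with designed protein coverage.

    Each protein gets one query transcript whose segments union to exactly
    the designed covered prefix [1, round(target * length)], split into
    ``n_segments`` overlapping pieces. ``coverage_profile`` gives the
    per-protein target coverage; the default draws targets uniformly from
    [0.5, 1.0]. Returns (segments, protein_lengths, planted_full_length) —
    the planted count tallies proteins whose *achieved* coverage (after
    rounding to whole residues) exceeds 0.9.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    if coverage_profile is None:
        coverage_profile = rng.uniform(0.5, 1.0, size=n_proteins)
    targets = np.asarray(coverage_profile, dtype=float)
    if targets.size != n_proteins:
        raise ValueError("coverage_profile length must equal n_proteins")
    if ((targets < 0) | (targets > 1)).any():
        raise ValueError("coverage targets must lie in [0, 1]")

    lo, hi = length_range
    segments: list[AlignmentSegment] = []
    protein_lengths: dict[str, int] = {}
    planted = 0
    for p in range(n_proteins):
        plen = int(rng.integers(lo, hi + 1))
        sid = f"prot{p:05d}"
        qid = f"contig{p:05d}"
        protein_lengths[sid] = plen
        covered = int(round(targets[p] * plen))
        if covered / plen > 0.9:
            planted += 1
        if covered == 0:
            continue
        bounds = np.linspace(0, covered, n_segments + 1).astype(int)
        for s in range(n_segments):
            start = int(bounds[s]) + 1
            end = int(bounds[s + 1])
            if end < start:
                continue
            # overlap adjacent pieces by up to 10 residues inside the prefix
            start = max(1, start - int(rng.integers(0, 11)))
            segments.append(
                AlignmentSegment(
                    query_id=qid,
                    subject_id=sid,
                    subject_start=start,
                    subject_end=end,
                    percent_identity=float(rng.uniform(90, 100)),
                    e_value=1e-30,
                )
            )
    return segments, protein_lengths, planted


def gen_assembly(
    n_contigs: int = 50,
    length_range: tuple[int, int] = (200, 3000),
    n_base_rate: float = 0.01,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], AssemblyStats]:
    """Simulate a contig set with planted length and N-base composition.

    Contig lengths are uniform over ``length_range``; each contig carries an
    exact count of ambiguous bases (``round(n_base_rate * length)``) at
    random positions. Returns the (id, sequence) list and the exact
    :class:`AssemblyStats` implied by the construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    lo, hi = length_range
    contigs: list[tuple[str, str]] = []
    lengths: list[int] = []
    total_n = 0
    for c in range(n_contigs):
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(list("ACGT"), size=length)
        k = int(round(n_base_rate * length))
        if k:
            pos = rng.choice(length, size=k, replace=False)
            seq[pos] = "N"
        contigs.append((f"contig{c:05d}", "".join(seq)))
        lengths.append(length)
        total_n += k
    stats = AssemblyStats(
        n_contigs=n_contigs,
        n_ge_1000=sum(1 for L in lengths if L >= 1000),
        total_length=sum(lengths),
        ambiguous_bases=total_n,
        n50=n50(lengths),
    )
    return contigs, stats


def table2_fixture() -> tuple[
    RawMetricMatrix, DatasetInfo, pd.DataFrame, pd.Series
]:
    """The bundled published worked example: one human paired-end dataset,
    ten assemblers, twenty metrics.

    Returns (raw_matrix, dataset_info, printed_normalized, printed_ms):
    the transcribed raw values as a :class:`RawMetricMatrix`, the dataset
    descriptor, the printed two-decimal normalized values (metrics x
    assemblers), and the printed per-assembler metric-score row — the
    latter two for tolerance-based regression checks.
    """
    rows = [
        (TABLE2_DATASET_ID, aid, mid, float(v))
        for mid, values in TABLE2_RAW.items()
        for aid, v in zip(TABLE2_ASSEMBLERS, values)
    ]
    raw = RawMetricMatrix(pd.DataFrame(rows, columns=list(COLUMNS)))
    info = DatasetInfo(
        dataset_id=TABLE2_DATASET_ID, layout=Layout.PAIRED_END, strand_specific=True
    )
    normalized = pd.DataFrame(
        TABLE2_NORMALIZED, index=list(TABLE2_ASSEMBLERS)
    ).T
    ms = pd.Series(list(TABLE2_MS), index=list(TABLE2_ASSEMBLERS), name="MS")
    return raw, info, normalized, ms
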