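"""Metric registry and dataset descriptors.

A *metric registry* lists the evaluation metrics an assembly benchmark draws
on: each entry records where the metric comes from (read re-mapping,
reference-based transcript statistics, read-support scores, ortholog
completeness), whether larger values mean better assemblies, and whether the
metric can be computed at all for a given sequencing layout (two read-support
metrics exist only for paired-end libraries).

The built-in registry holds the canonical 20-metric panel used for
cross-assembler comparison. Six of its metrics are penalties (misassemblies,
per-transcript mismatches, duplication ratio, uncovered bases, ambiguous
bases, missing orthologs) and are inverted during normalization.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence


class Direction(str, enum.Enum):
    """Orientation of a metric: do larger raw values indicate quality?"""

    HIGHER_BETTER = "higher_better"
    LOWER_BETTER = "lower_better"


class Applicability(str, enum.Enum):
    """Whether a metric exists for every library layout or only paired-end."""

    ALL = "all"
    PAIRED_END_ONLY = "paired_end_only"


class Layout(str, enum.Enum):
    SINGLE_END = "single_end"
    PAIRED_END = "paired_end"


@dataclass(frozen=True)
class MetricDefinition:
    """One evaluation metric: identity, provenance, orientation, scope."""

    metric_id: str
    label: str
    source_tool: str
    direction: Direction
    applicability: Applicability = Applicability.ALL
    ordinal: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", Direction(self.direction))
        object.__setattr__(self, "applicability", Applicability(self.applicability))


@dataclass(frozen=True)
class DatasetInfo:
    """One RNA-Seq dataset entering the comparison.

    ``replicate_group`` labels near-identical datasets (e.g. time points of
    the same infection experiment) whose per-dataset scores are averaged
    before entering the overall score, so a repeated experiment is not
    over-weighted.
    """

    dataset_id: str
    layout: Layout = Layout.PAIRED_END
    strand_specific: bool = False
    replicate_group: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "layout", Layout(self.layout))
        if self.replicate_group == "":
            object.__setattr__(self, "replicate_group", None)


_BUILTIN = (
    # (metric_id, label, source_tool, direction, applicability)
    ("overall_mapping_rate", "Overall mapping rate", "HISAT2", "higher_better", "all"),
    ("transcripts_ge_1000nt", "Transcripts >=1,000 nt", "rnaQUAST", "higher_better", "all"),
    ("misassemblies", "Misassemblies", "rnaQUAST", "lower_better", "all"),
    ("mismatches_per_transcript", "Mismatches per transcript", "rnaQUAST", "lower_better", "all"),
    ("avg_alignment_length", "Average alignment length", "rnaQUAST", "higher_better", "all"),
    ("pct95_assembled_isoforms", "95%-assembled isoforms", "rnaQUAST", "higher_better", "all"),
    ("duplication_ratio", "Duplication ratio", "rnaQUAST", "lower_better", "all"),
    ("ex90n50", "Ex90N50", "Trinity/Salmon", "higher_better", "all"),
    ("full_length_transcripts", "Full-length transcripts", "Trinity/Blastx", "higher_better", "all"),
    ("reference_coverage", "Reference coverage", "TransRate", "higher_better", "all"),
    ("mean_orf_percentage", "Mean ORF percentage", "TransRate", "higher_better", "all"),
    ("transrate_optimal_score", "Optimal score", "TransRate", "higher_better", "paired_end_only"),
    ("pct_bases_uncovered", "Percentage bases uncovered", "TransRate", "lower_better", "paired_end_only"),
    ("ambiguous_bases", "Number of ambiguous bases", "TransRate", "lower_better", "all"),
    ("nucleotide_f1", "Nucleotide F1", "DETONATE", "higher_better", "all"),
    ("contig_f1", "Contig F1", "DETONATE", "higher_better", "all"),
    ("kc_score", "KC score", "DETONATE", "higher_better", "all"),
    ("rsem_eval", "RSEM-EVAL", "DETONATE", "higher_better", "all"),
    ("complete_buscos", "Complete BUSCOs", "BUSCO", "higher_better", "all"),
    ("missing_buscos", "Missing BUSCOs", "BUSCO", "lower_better", "all"),
)


def builtin_registry() -> list[MetricDefinition]:
    """Return the canonical 20-metric panel in its standard order.

    The panel covers read re-mapping (1 metric), reference-based transcript
    statistics (6), expression-informed contig length (1), protein
    full-length reconstruction (1), read-support scores (5), model-based
    assembly likelihood and k-mer statistics (4, counting the F1 pair), and
    ortholog completeness (2). Two read-support metrics are paired-end only.
    """
    return [
        MetricDefinition(mid, label, tool, direction, applicability, ordinal=i + 1)
        for i, (mid, label, tool, direction, applicability) in enumerate(_BUILTIN)
    ]


def applicable_metrics(
    dataset: DatasetInfo, registry: Sequence[MetricDefinition]
) -> set[str]:
    """Metric ids computable for ``dataset`` given its sequencing layout.

    Paired-end datasets can use the full registry; single-end datasets lose
    the paired-end-only metrics (so the canonical panel shrinks from 20 to
    18 applicable metrics).
    """
    paired = dataset.layout is Layout.PAIRED_END
    return {
        m.metric_id
        for m in registry
        if m.applicability is Applicability.ALL
        or (m.applicability is Applicability.PAIRED_END_ONLY and paired)
    }


@dataclass
class ValidationReport:
    """Report-only result of checking a raw matrix against registry/datasets.

    ``non_normalizable`` lists (dataset, metric) pairs with fewer than two
    non-missing assembler values — min-max normalization over a single value
    is degenerate. ``coverage`` counts non-missing cells per dataset.
    """

    unknown_metrics: list[str] = field(default_factory=list)
    unknown_datasets: list[str] = field(default_factory=list)
    not_applicable: list[tuple[str, str]] = field(default_factory=list)
    non_normalizable: list[tuple[str, str]] = field(default_factory=list)
    missing_cells: list[tuple[str, str, str]] = field(default_factory=list)
    coverage: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not (
            self.unknown_metrics
            or self.unknown_datasets
            or self.not_applicable
            or self.non_normalizable
        )

    def problems(self) -> list[str]:
        out = []
        for m in self.unknown_metrics:
            out.append(f"unknown metric id: {m}")
        for d in self.unknown_datasets:
            out.append(f"unknown dataset id: {d}")
        for d, m in self.not_applicable:
            out.append(f"value present for non-applicable metric {m} in dataset {d}")
        for d, m in self.non_normalizable:
            out.append(f"metric {m} has <2 values in dataset {d}: not normalizable")
        return out


def validate_matrix(
    matrix,
    registry: Sequence[MetricDefinition],
    datasets: Optional[Iterable[DatasetInfo]] = None,
) -> ValidationReport:
    """Check a raw metric matrix against a registry and dataset sheet.

    Never mutates the matrix; all findings are reported. Missing cells (an
    assembler lacking a value other assemblers have) are listed for
    information only — how they score is a policy of the scoring step.
    """
    report = ValidationReport()
    known_metrics = {m.metric_id for m in registry}
    ds_by_id: Mapping[str, DatasetInfo] = (
        {d.dataset_id: d for d in datasets} if datasets is not None else {}
    )

    for mid in matrix.metrics:
        if mid not in known_metrics:
            report.unknown_metrics.append(mid)
    if ds_by_id:
        for did in matrix.datasets:
            if did not in ds_by_id:
                report.unknown_datasets.append(did)

    for did in matrix.datasets:
        ds = ds_by_id.get(did)
        allowed = applicable_metrics(ds, registry) if ds is not None else known_metrics
        wide = matrix.pivot(did)  # metrics x assemblers, NaN for missing
        report.coverage[did] = int(wide.notna().to_numpy().sum())
        for mid in wide.index:
            row = wide.loc[mid]
            n_present = int(row.notna().sum())
            if mid in known_metrics and mid not in allowed and n_present > 0:
                report.not_applicable.append((did, mid))
                continue
            if 0 < n_present < 2:
                report.non_normalizable.append((did, mid))
            for aid in row.index[row.isna()]:
                if n_present > 0:
                    report.missing_cells.append((did, aid, mid))
    return report
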