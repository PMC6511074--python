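"""File readers and writers for the evaluation pipeline.

Canonical interchange is long-format TSV (``dataset assembler metric
value``); wide tables are ambiguous once metrics can be missing per dataset.
Registry and dataset sheets are TSV (YAML accepted for the registry), all
other inputs are the field's standard text formats: FASTA, 12-column tabular
alignments (BLAST ``-outfmt 6``), plain expression tables, BUSCO
short-summary text.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import pandas as pd
import yaml
from Bio import SeqIO

from .derived import (
    AlignmentSegment,
    BuscoCounts,
    TranscriptExpressionRecord,
    parse_busco_summary,
)
from .matrix import COLUMNS, RawMetricMatrix
from .registry import DatasetInfo, MetricDefinition
from .scoring import ScoreTable

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_NA_TOKENS = {"", "NA", "na", "NaN", "nan", "N/A", "."}


def read_metric_matrix(path: PathLike) -> RawMetricMatrix:
    """Read a long-format metric matrix TSV.

    Header must be ``dataset assembler metric value``; empty or NA-like
    value fields become missing cells (with a logged warning); duplicate
    (dataset, assembler, metric) triples are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: malformed header, missing columns {missing}")
    na_mask = df["value"].isin(_NA_TOKENS)
    if na_mask.any():
        logger.warning(
            "%s: %d missing value cells (NA/empty)", path, int(na_mask.sum())
        )
    df.loc[na_mask, "value"] = "nan"
    try:
        df["value"] = df["value"].astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: unparsable value field: {exc}") from exc
    return RawMetricMatrix(df)


def write_metric_matrix(matrix: RawMetricMatrix, path: PathLike) -> None:
    matrix.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_registry(path: PathLike) -> list[MetricDefinition]:
    """Read a metric registry from TSV or YAML.

    TSV header: ``metric_id label source_tool direction applicability
    ordinal``. YAML: a list of mappings with the same keys.
    """
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        entries = yaml.safe_load(path.read_text())
    else:
        entries = pd.read_csv(path, sep="\t", dtype=str).to_dict("records")
    out = []
    for e in entries:
        out.append(
            MetricDefinition(
                metric_id=str(e["metric_id"]),
                label=str(e.get("label", e["metric_id"])),
                source_tool=str(e.get("source_tool", "")),
                direction=str(e["direction"]),
                applicability=str(e.get("applicability", "all")),
                ordinal=int(e.get("ordinal", 0)),
            )
        )
    ids = [m.metric_id for m in out]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate metric ids in registry")
    return out


def read_datasets(path: PathLike) -> list[DatasetInfo]:
    """Read a dataset sheet TSV: ``dataset_id layout strand_specific
    replicate_group`` (empty replicate_group means ungrouped)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "dataset_id" not in df.columns or "layout" not in df.columns:
        raise ValueError(f"{path}: dataset sheet needs dataset_id and layout columns")
    out = []
    for _, row in df.iterrows():
        out.append(
            DatasetInfo(
                dataset_id=row["dataset_id"],
                layout=row["layout"],
                strand_specific=str(row.get("strand_specific", "false")).lower()
                in ("1", "true", "yes"),
                replicate_group=row.get("replicate_group", "") or None,
            )
        )
    ids = [d.dataset_id for d in out]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate dataset ids")
    return out


def read_fasta(path: PathLike) -> Iterator[tuple[str, str]]:
    """Iterate (id, sequence) pairs from a (multi-line) FASTA file."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, str(rec.seq)


def write_fasta(contigs: Sequence[tuple[str, str]], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in contigs:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


OUTFMT6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def read_alignments(
    path: PathLike, max_evalue: Optional[float] = None
) -> list[AlignmentSegment]:
    """Read a 12-column tabular alignment file (BLAST ``-outfmt 6``).

    Subject coordinates may be reversed in the file; they are canonicalized.
    ``max_evalue`` applies an optional e-value pre-filter (off by default).
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=OUTFMT6_COLUMNS,
        float_precision="round_trip",
    )
    if max_evalue is not None:
        df = df[df["evalue"] <= max_evalue]
    return [
        AlignmentSegment(
            query_id=str(r.qseqid),
            subject_id=str(r.sseqid),
            subject_start=int(r.sstart),
            subject_end=int(r.send),
            percent_identity=float(r.pident),
            e_value=float(r.evalue),
        )
        for r in df.itertuples()
    ]


def write_alignments(segments: Sequence[AlignmentSegment], path: PathLike) -> None:
    """Write segments as a 12-column tabular alignment file (synthetic
    query coordinates: 1..segment length)."""
    with open(path, "w") as fh:
        for s in segments:
            aln_len = s.subject_end - s.subject_start + 1
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        s.query_id,
                        s.subject_id,
                        f"{s.percent_identity:.2f}",
                        aln_len,
                        0,
                        0,
                        1,
                        aln_len * 3,
                        s.subject_start,
                        s.subject_end,
                        f"{s.e_value:.2g}",
                        aln_len * 2,
                    )
                )
                + "\n"
            )


def read_protein_lengths(path: PathLike) -> dict[str, int]:
    """Read a two-column TSV ``subject_id length`` (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if cols[:2] != ["subject_id", "length"]:
        # headerless: first row is data
        df = pd.read_csv(path, sep="\t", header=None, names=["subject_id", "length"], dtype=str)
    return {str(r.subject_id): int(r.length) for r in df.itertuples()}


def write_protein_lengths(lengths: dict[str, int], path: PathLike) -> None:
    pd.DataFrame(
        {"subject_id": list(lengths), "length": list(lengths.values())}
    ).to_csv(path, sep="\t", index=False)


def read_expression_table(path: PathLike) -> list[TranscriptExpressionRecord]:
    """Read a TSV ``transcript_id length expression``."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    needed = {"transcript_id", "length", "expression"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: expression table needs columns {sorted(needed)}")
    return [
        TranscriptExpressionRecord(
            str(r.transcript_id), int(r.length), float(r.expression)
        )
        for r in df.itertuples()
    ]


def write_expression_table(
    records: Sequence[TranscriptExpressionRecord], path: PathLike
) -> None:
    pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in records],
            "length": [r.length for r in records],
            "expression": [r.expression for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_busco_summary(path: PathLike) -> BuscoCounts:
    return parse_busco_summary(Path(path).read_text())


def write_score_report(
    table: ScoreTable,
    out_dir: PathLike,
    normalized: Optional[RawMetricMatrix] = None,
    warnings_list: Optional[Sequence[str]] = None,
) -> dict[str, Path]:
    """Write the score tables (TSV) and a JSON bundle into ``out_dir``.

    Emits ``normalized.tsv`` (long format, if given), ``ms.tsv`` (datasets x
    assemblers plus a max_possible column), ``oms.tsv`` and ``report.json``
    with all tables, the ranking and collected warnings. Returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if normalized is not None:
        paths["normalized"] = out / "normalized.tsv"
        write_metric_matrix(normalized, paths["normalized"])

    ms = table.ms.copy()
    ms.insert(0, "max_possible", table.max_possible)
    paths["ms"] = out / "ms.tsv"
    ms.to_csv(paths["ms"], sep="\t", float_format="%.10g")

    paths["oms"] = out / "oms.tsv"
    table.oms.to_frame().to_csv(paths["oms"], sep="\t", float_format="%.10g")

    paths["report"] = out / "report.json"
    bundle = {
        "ms": {d: {a: table.ms.loc[d, a] for a in table.ms.columns} for d in table.ms.index},
        "max_possible": table.max_possible.to_dict(),
        "oms": table.oms.to_dict(),
        "ranking": table.ranking,
        "warnings": list(warnings_list or []),
    }
    paths["report"].write_text(json.dumps(bundle, indent=2, sort_keys=True) + "\n")
    return paths


def read_score_report(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())


def plot_ms_heatmap(
    table: ScoreTable,
    leaf_order: Optional[Sequence[str]] = None,
    path: Optional[PathLike] = None,
):
    """Render the MS heatmap: assemblers (rows, cluster order) x datasets.

    Cells are annotated with the MS rounded to two decimals; row labels
    carry the assembler's OMS in brackets. Returns the matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    order = list(leaf_order) if leaf_order is not None else list(table.ms.columns)
    data = table.ms.T.loc[order]
    labels = [f"{a} [{table.oms[a]:.1f}]" for a in order]
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.9 * data.shape[1], 0.8 + 0.45 * data.shape[0])
    )
    sns.heatmap(
        data,
        annot=True,
        fmt=".2f",
        cmap="viridis",
        yticklabels=labels,
        cbar_kws={"label": "metric score (MS)"},
        ax=ax,
    )
    ax.set_xlabel("dataset")
    ax.set_ylabel("assembler [OMS]")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
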