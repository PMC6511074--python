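"""Assembly statistics computed from primary data.

These are the evaluation metrics the pipeline computes itself rather than
ingesting from external evaluators: contig-length statistics (N50 and the
expression-informed ExN50), the number of reference proteins reconstructed
at (nearly) full length from tabular protein alignments, basic per-assembly
counts (contigs, long contigs, ambiguous bases), and completeness summaries
of universal single-copy ortholog (BUSCO) classifications.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np


@dataclass(frozen=True)
class TranscriptExpressionRecord:
    """One assembled transcript with length (nt) and normalized abundance."""

    transcript_id: str
    length: int
    expression: float

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"transcript {self.transcript_id}: length must be >= 1")
        if self.expression < 0:
            raise ValueError(
                f"transcript {self.transcript_id}: expression must be >= 0"
            )


@dataclass(frozen=True)
class AlignmentSegment:
    """One transcript-to-protein alignment segment in subject coordinates.

    Coordinates are 1-based inclusive amino-acid positions on the protein;
    reversed coordinates (start > end) are canonicalized by swapping.
    """

    query_id: str
    subject_id: str
    subject_start: int
    subject_end: int
    percent_identity: float = 100.0
    e_value: float = 0.0

    def __post_init__(self) -> None:
        s, e = self.subject_start, self.subject_end
        if s > e:
            object.__setattr__(self, "subject_start", e)
            object.__setattr__(self, "subject_end", s)
        if self.subject_start < 1:
            raise ValueError("subject coordinates must be >= 1")


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    n_ge_1000: int
    total_length: int
    ambiguous_bases: int
    n50: int


@dataclass(frozen=True)
class BuscoCounts:
    """Universal single-copy ortholog classification counts."""

    single_copy: int
    duplicated: int
    fragmented: int
    missing: int
    total: int

    def __post_init__(self) -> None:
        s = self.single_copy + self.duplicated + self.fragmented + self.missing
        if s != self.total:
            raise ValueError(
                f"BUSCO categories sum to {s}, expected total {self.total}"
            )


def n50(lengths: Sequence[int]) -> int:
    """N50: the contig length at which the descending cumulative length
    first reaches half the total assembled length."""
    arr = np.asarray(lengths, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("n50 of an empty length list is undefined")
    if (arr <= 0).any():
        raise ValueError("contig lengths must be positive")
    arr = np.sort(arr)[::-1]
    half = arr.sum() / 2.0
    idx = int(np.searchsorted(np.cumsum(arr), half))
    return int(arr[idx])


def exn50(
    records: Sequence[TranscriptExpressionRecord], fraction: float = 0.9
) -> int:
    """Expression-informed N50 (Ex90N50 at the default fraction).

    Restricts the N50 computation to the smallest set of most highly
    expressed transcripts accounting for ``fraction`` of the total
    normalized expression, which keeps hordes of short, weakly expressed
    contigs from dragging the N50 down. Expression is renormalized to
    proportions internally, so the statistic is unit-invariant (TPM,
    estimated counts, ...). Expression ties are broken by length
    (descending) then id (ascending) for determinism.
    """
    if not records:
        raise ValueError("exn50 of an empty record list is undefined")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    total = float(sum(r.expression for r in records))
    if total <= 0:
        raise ValueError("total expression is zero: exn50 undefined")
    ordered = sorted(records, key=lambda r: (-r.expression, -r.length, r.transcript_id))
    cum = 0.0
    prefix: list[int] = []
    for r in ordered:
        prefix.append(r.length)
        cum += r.expression / total
        if cum >= fraction - 1e-12:
            break
    return n50(prefix)


def _interval_union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total positions covered by a union of 1-based inclusive intervals."""
    ivs = sorted(intervals)
    covered = 0
    cur_start, cur_end = None, None
    for s, e in ivs:
        if cur_end is None or s > cur_end + 1:
            if cur_end is not None:
                covered += cur_end - cur_start + 1
            cur_start, cur_end = s, e
        elif e > cur_end:
            cur_end = e
    if cur_end is not None:
        covered += cur_end - cur_start + 1
    return covered


def protein_coverage(
    segments: Iterable[AlignmentSegment],
    protein_lengths: Mapping[str, int],
) -> dict[str, float]:
    """Best per-protein length coverage by any single transcript.

    Segments of one transcript aligning to one protein are grouped and
    their subject intervals unioned (discontinuous alignments of the same
    transcript jointly cover the protein); each protein then reports the
    maximum coverage over transcripts — coverage is never pooled across
    different transcripts. Values are fractions in [0, 1], capped at 1.
    """
    per_pair: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for seg in segments:
        if seg.subject_id not in protein_lengths:
            raise KeyError(f"unknown protein length for subject {seg.subject_id}")
        per_pair.setdefault((seg.query_id, seg.subject_id), []).append(
            (seg.subject_start, seg.subject_end)
        )
    best: dict[str, float] = {}
    for (qid, sid), ivs in per_pair.items():
        plen = protein_lengths[sid]
        if plen <= 0:
            raise ValueError(f"non-positive protein length for {sid}")
        cov = min(1.0, _interval_union_length(ivs) / plen)
        if cov > best.get(sid, -1.0):
            best[sid] = cov
    return best


def count_full_length(
    coverages: Mapping[str, float],
    threshold: float = 0.9,
    strict: bool = True,
) -> int:
    """Count proteins reconstructed at (nearly) full length.

    A protein counts as full-length when its best single-transcript
    coverage exceeds ``threshold`` (strictly by default: coverage must be
    > 90%, so exactly-90% does not count).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if strict:
        return sum(1 for c in coverages.values() if c > threshold)
    return sum(1 for c in coverages.values() if c >= threshold)


_VALID_BASES = frozenset("ACGTN")


def assembly_stats(sequences: Iterable[tuple[str, str]]) -> AssemblyStats:
    """Basic per-assembly statistics from (id, sequence) pairs.

    Counts contigs, contigs of at least 1,000 nt, total length, ambiguous
    bases (N, case-insensitive), and the N50. Characters outside
    {A,C,G,T,N} trigger a warning and count toward length but not toward
    the ambiguous-base tally.
    """
    lengths: list[int] = []
    n_ge_1000 = 0
    ambiguous = 0
    odd_chars: set[str] = set()
    for _sid, seq in sequences:
        up = seq.upper()
        lengths.append(len(up))
        if len(up) >= 1000:
            n_ge_1000 += 1
        ambiguous += up.count("N")
        extra = set(up) - _VALID_BASES
        odd_chars |= extra
    if not lengths:
        raise ValueError("empty assembly")
    if odd_chars:
        warnings.warn(
            f"characters outside ACGTN encountered: {sorted(odd_chars)}",
            stacklevel=2,
        )
    return AssemblyStats(
        n_contigs=len(lengths),
        n_ge_1000=n_ge_1000,
        total_length=int(sum(lengths)),
        ambiguous_bases=ambiguous,
        n50=n50(lengths),
    )


def busco_complete(counts: BuscoCounts) -> tuple[int, int]:
    """Summarize ortholog completeness as (complete_total, missing).

    ``complete_total`` merges complete single-copy and complete duplicated
    orthologs — duplicated hits often reflect genuine alternative
    transcripts rather than assembly errors, so both count as recovered.
    """
    return counts.single_copy + counts.duplicated, counts.missing


_ONE_LINE_RE = re.compile(
    r"C:\s*(?P<c>[\d.]+)%\[S:\s*(?P<s>[\d.]+)%,\s*D:\s*(?P<d>[\d.]+)%\],"
    r"F:\s*(?P<f>[\d.]+)%,M:\s*(?P<m>[\d.]+)%,n:\s*(?P<n>\d+)"
)

_COUNT_PATTERNS = {
    "single_copy": re.compile(r"^\s*(\d+)\s+Complete and single-copy BUSCOs", re.M),
    "duplicated": re.compile(r"^\s*(\d+)\s+Complete and duplicated BUSCOs", re.M),
    "fragmented": re.compile(r"^\s*(\d+)\s+Fragmented BUSCOs", re.M),
    "missing": re.compile(r"^\s*(\d+)\s+Missing BUSCOs", re.M),
    "total": re.compile(r"^\s*(\d+)\s+Total BUSCO groups searched", re.M),
}


def parse_busco_summary(text: str) -> BuscoCounts:
    """Parse a BUSCO short-summary text into category counts.

    Prefers the per-category count lines; falls back to the one-line
    percentage summary (``C:..%[S:..%,D:..%],F:..%,M:..%,n:N``), converting
    percentages to counts via n and assigning any rounding remainder to the
    missing category so the counts sum to the total.
    """
    found = {k: p.search(text) for k, p in _COUNT_PATTERNS.items()}
    if all(found.values()):
        vals = {k: int(m.group(1)) for k, m in found.items()}
        return BuscoCounts(
            single_copy=vals["single_copy"],
            duplicated=vals["duplicated"],
            fragmented=vals["fragmented"],
            missing=vals["missing"],
            total=vals["total"],
        )
    m = _ONE_LINE_RE.search(text.replace(" ", ""))
    if m is None:
        raise ValueError("unrecognized BUSCO short-summary format")
    n = int(m.group("n"))
    s = round(float(m.group("s")) / 100.0 * n)
    d = round(float(m.group("d")) / 100.0 * n)
    f = round(float(m.group("f")) / 100.0 * n)
    miss = n - s - d - f
    return BuscoCounts(
        single_copy=s, duplicated=d, fragmented=f, missing=miss, total=n
    )
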