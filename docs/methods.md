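# Methods

## Scoring model and assumptions

The pipeline aggregates a panel of heterogeneous assembly-quality metrics
into a single comparable score per (dataset, assembler). The only modelling
assumption is ordinal: within one dataset and one metric, a better raw value
means a better assembly, and the min–max normalized value

    n_k = (v_k − min v) / (max v − min v)        (quality metrics)
    n_k = (max v − v_k) / (max v − min v)        (penalty metrics)

is a fair exchange rate between metrics. Nothing is assumed about metric
scales or distributions — normalization is invariant under positive affine
transformations of the raw vector, which is also why it coincides with
z-scoring followed by rescaling into [0, 1]. The cost of this robustness is
that normalized scores are *relative to the compared set*: adding or
removing an assembler changes everyone's scores, and a metric's full [0, 1]
range is spent even when the raw spread is trivial. Metrics are equally
weighted by construction; weighting schemes for correlated metrics are
deliberately out of scope (the panel was curated instead).

The metric score MS(d, a) is the sum of the normalized scores over the
metrics applicable to dataset d; its maximum is the applicable-metric count
(20 for paired-end layouts with the built-in registry, 18 for single-end,
because the TransRate optimal score and the uncovered-base percentage
require paired-end reads). The overall metric score OMS(a) sums MS over
datasets, except that datasets sharing a replicate group contribute their
arithmetic mean once. Ranking is by descending OMS with lexicographic
tie-breaks, making output deterministic.

## Metric registry

The built-in registry fixes each metric's orientation and applicability.
Orientation is not something the normalization formula can know; it is
domain knowledge (misassemblies are bad, mapping rates are good). The six
penalty metrics are misassemblies, mismatches per transcript, duplication
ratio, percentage of uncovered bases, ambiguous bases, and missing BUSCOs.
The registry test suite cross-checks every orientation arithmetically
against the bundled published worked-example table: for each metric row,
only one orientation reproduces the printed normalized values. User
registries (TSV or YAML) can override the panel entirely.

## Policy knobs (all configurable; defaults chosen for fairness)

- **Degenerate metric vectors** (max = min): every assembler receives 0.5.
  A constant metric carries no ranking information; a neutral score keeps
  it from distorting MS totals, while 0.0 (available via
  `degenerate_value`) treats non-discrimination as failure. A warning is
  logged either way.
- **Missing single-assembler cells**: default policy `"zero"` — an
  assembler that failed to produce a metric is scored as the worst
  (contribution 0); `"omit"` excludes the cell from that assembler's sum
  instead. Missing cells never enter the min/max of the others.
- **Incomplete replicate groups** average over the members that have MS
  values.
- **Clustering** of MS profiles uses Euclidean distance with average
  linkage (conventional defaults; both configurable). It is a display
  aid for the heatmap's row order and never feeds back into MS or OMS.
- **Rounding**: all arithmetic runs at full float precision; two-decimal
  rounding happens only at report time.

## Derived metrics

- **N50**: the contig length at which the descending cumulative length
  first reaches half the total.
- **ExN50** (default fraction 0.9, i.e. Ex90N50): N50 restricted to the
  smallest set of most highly expressed transcripts reaching 90% of total
  expression. Expression is renormalized to proportions internally, so the
  statistic is unit-invariant (TPM vs estimated counts does not matter).
  The transcript crossing the 90% boundary is included. Expression ties
  are broken by length (descending) then id (ascending) so output is
  deterministic.
- **Full-length protein reconstruction**: alignment segments are grouped
  per (transcript, protein) pair and their subject-coordinate intervals
  (1-based inclusive) unioned; a protein's coverage is the *maximum* over
  transcripts — coverage is never pooled across transcripts, since two
  half-transcripts do not make a full-length reconstruction. A protein
  counts as full-length when coverage strictly exceeds the threshold
  (default 0.9). The per-pair interval union is a deliberate
  simplification of colinearity-aware segment chaining: it ignores segment
  order and strand consistency on the query, which can only over-count
  coverage for pathologically rearranged transcripts. Reversed subject
  coordinates are canonicalized by swapping. E-value/identity filtering is
  the caller's concern; the CLI applies an e ≤ 1e-20 pre-filter by
  default, the library API does not.
- **Assembly statistics**: contig count, contigs ≥ 1,000 nt, total length,
  ambiguous bases (N, case-insensitive), N50. Characters outside ACGTN
  warn and count toward length only.
- **BUSCO summary**: complete = single-copy + duplicated (duplicated hits
  usually reflect alternative transcripts, not errors); missing is passed
  through. The parser prefers per-category count lines and falls back to
  the one-line percentage form, assigning the rounding remainder to the
  missing category so counts always sum to the total.

## Synthetic data

The generators emulate the statistical structure the scoring analysis
assumes, with ground truth returned alongside the data:

- `gen_metric_matrix` plants a strictly decreasing assembler-quality vector
  and observes it through per-(dataset, metric) affine links (random offset
  and scale, sign flipped for penalty metrics) plus Gaussian noise on the
  quality scale. Defaults — 9 datasets, 10 assemblers, quality spread 1.0,
  noise sd 0.1 — describe a benchmark of clearly separated tools with
  occasional metric-level rank flips. At noise sd 0, OMS ranking provably
  recovers the planted order; tests assert exactly that.
- `gen_transcripts` supports the two expression designs with closed-form
  ExN50 ground truth: a dominant transcript carrying >90% of expression
  (expected value = its length, 500 nt by default, against a longer
  background) and a uniform design (expected value = the common length).
  Intermediate skews are rejected rather than given a guessed truth.
- `gen_alignments` emits segments whose union is exactly a designed covered
  prefix of each protein, split into overlapping pieces; the planted
  full-length count is derived from the achieved (residue-rounded)
  coverage.
- `gen_assembly` plants exact contig lengths and ambiguous-base counts.

All generators derive independent streams from one master seed via
`numpy.random.SeedSequence.spawn`, so outputs are reproducible and
component-wise decoupled.

What the synthetic matrices do *not* emulate: metric-metric correlations,
heavy-tailed or discrete raw-score distributions, dataset-specific
difficulty, and missing cells. Passing the rank-recovery and bounds tests
therefore shows the aggregation logic is correct, not that 20 real metrics
contain enough signal to rank real assemblers — that evidence comes from
the bundled published table.

## Numerical and regression-test choices

Published raw values are printed rounded (some to two decimals over ranges
below 0.3), so recomputed normalized scores can differ from printed ones by
up to half a print quantum divided by the metric's range. Regression tests
use ±0.02 per normalized cell and ±0.06 per MS where the printed precision
supports it, and ±0.04 for the three coarsely printed metric rows
(reference coverage, contig F1, k-mer compression score). Score sums use
full precision; comparisons at 1e-12 are against a brute-force evaluation
of the same definition. The cumulative-expression threshold in ExN50 uses
a 1e-12 slack so that proportions summing to 0.9 by construction are not
missed to float rounding.

## Problem sizes in tests

The test and acceptance workloads are intentionally small — the bundled
10 × 20 table, synthetic matrices up to 10 assemblers × 9 datasets × 20
metrics, and derived-metric instances up to a few hundred items — which is
the scale at which every expected value is either published, analytically
planted, or brute-force verifiable. The pipeline itself is vectorized over
pandas frames and has no intrinsic size limit.

## Known limitations

- Relative scoring: MS values are not comparable across different
  assembler sets or registries.
- Equal metric weights; correlated metrics (e.g. complete BUSCOs and
  full-length transcript counts) can double-count one strength.
- The interval-union full-length procedure is colinearity-blind (above).
- No significance testing on rank differences; a one-point OMS gap is not
  evidence.
- External evaluator metrics (TransRate, RSEM-EVAL, rnaQUAST statistics,
  BUSCO searches, read mapping) are ingested, never recomputed.
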