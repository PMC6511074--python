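"""Published worked example: raw and normalized evaluation metrics for one
human paired-end RNA-Seq library assembled by ten de novo assemblers.

Raw values are the printed (rounded) numbers; the RSEM-EVAL score is in units
of 1e9 and the ambiguous-base count in millions, exactly as printed. The
normalized values and the summarized metric-score (MS) row are the printed
two-decimal figures and serve as regression anchors for the scoring pipeline
(tolerances absorb print rounding).
"""

from __future__ import annotations

TABLE2_DATASET_ID = "hsa"

TABLE2_ASSEMBLERS = (
    "Trinity",
    "Oases",
    "Trans-ABySS",
    "SOAPdenovo-Trans",
    "Bridger",
    "BinPacker",
    "IDBA-Tran",
    "Shannon",
    "SPAdes-sc",
    "SPAdes-rna",
)

# metric_id -> raw values, one per assembler in TABLE2_ASSEMBLERS order
TABLE2_RAW = {
    "overall_mapping_rate": (91.9, 88.04, 98.34, 89.93, 86.83, 72.6, 64.61, 84.27, 92.04, 95.95),
    "transcripts_ge_1000nt": (64061, 207474, 59779, 27529, 43201, 22611, 23516, 31328, 31039, 49860),
    "misassemblies": (3378, 216127, 2743, 279, 7329, 5603, 302, 2837, 2022, 5126),
    "mismatches_per_transcript": (1.38, 1.25, 0.57, 0.27, 1.44, 4.63, 0.67, 1.26, 0.8, 1.25),
    "avg_alignment_length": (795.23, 343.48, 246.85, 218, 654.41, 2335.73, 487.11, 711.83, 410.22, 412.24),
    "pct95_assembled_isoforms": (6788, 868, 6824, 2264, 2105, 2824, 709, 242, 1755, 3253),
    "duplication_ratio": (2.396, 2.355, 1.743, 1.187, 1.708, 2.389, 1.012, 1.53, 1.015, 1.192),
    "ex90n50": (326, 666, 441, 711, 1370, 2381, 708, 1324, 1186, 782),
    "full_length_transcripts": (8930, 8024, 9110, 6806, 8440, 4456, 2783, 6758, 5676, 7155),
    "reference_coverage": (0.23, 0.09, 0.26, 0.09, 0.09, 0.07, 0.08, 0.0, 0.08, 0.11),
    "mean_orf_percentage": (50.82, 42.09, 51.92, 48.02, 45.1, 42.57, 52.46, 55.7, 46.13, 46.25),
    "transrate_optimal_score": (0.13, 0.02, 0.11, 0.27, 0.14, 0.07, 0.25, 0.07, 0.4, 0.23),
    "pct_bases_uncovered": (0.59, 0.94, 0.63, 0.33, 0.42, 0.84, 0.02, 0.5, 0.03, 0.21),
    "ambiguous_bases": (286, 843, 437, 241, 206, 72, 138, 117, 177, 294),
    "nucleotide_f1": (0.43, 0.18, 0.51, 0.57, 0.48, 0.15, 0.55, 0.35, 0.61, 0.62),
    "contig_f1": (0.02, 0.02, 0.2, 0.21, 0.01, 0.0, 0.02, 0.02, 0.01, 0.01),
    "kc_score": (0.51, 0.24, 0.55, 0.37, 0.4, 0.37, 0.29, 0.42, 0.39, 0.43),
    "rsem_eval": (-6.51, -11.82, -6.26, -9.03, -7.72, -10.03, -16.3, -8.96, -12.12, -7.16),
    "complete_buscos": (4004, 3588, 4106, 2625, 3909, 2009, 1682, 3385, 2625, 3089),
    "missing_buscos": (1804, 1922, 1770, 2164, 1812, 4078, 2615, 2133, 2268, 1949),
}

# metric_id -> printed (0,1)-normalized values, same order
TABLE2_NORMALIZED = {
    "overall_mapping_rate": (0.81, 0.69, 1.00, 0.75, 0.66, 0.24, 0.00, 0.58, 0.81, 0.93),
    "transcripts_ge_1000nt": (0.22, 1.00, 0.20, 0.03, 0.11, 0.00, 0.00, 0.05, 0.05, 0.15),
    "misassemblies": (0.99, 0.00, 0.99, 1.00, 0.97, 0.98, 1.00, 0.99, 0.99, 0.98),
    "mismatches_per_transcript": (0.74, 0.77, 0.93, 1.00, 0.73, 0.00, 0.91, 0.77, 0.88, 0.78),
    "avg_alignment_length": (0.27, 0.06, 0.01, 0.00, 0.21, 1.00, 0.13, 0.23, 0.09, 0.09),
    "pct95_assembled_isoforms": (0.99, 0.10, 1.00, 0.31, 0.28, 0.39, 0.07, 0.00, 0.23, 0.46),
    "duplication_ratio": (0.00, 0.03, 0.47, 0.87, 0.50, 0.01, 1.00, 0.63, 1.00, 0.87),
    "ex90n50": (0.00, 0.17, 0.06, 0.19, 0.51, 1.00, 0.19, 0.49, 0.42, 0.22),
    "full_length_transcripts": (0.97, 0.83, 1.00, 0.64, 0.89, 0.26, 0.00, 0.63, 0.46, 0.69),
    "reference_coverage": (0.87, 0.33, 1.00, 0.34, 0.31, 0.27, 0.31, 0.00, 0.30, 0.42),
    "mean_orf_percentage": (0.64, 0.00, 0.72, 0.44, 0.22, 0.04, 0.76, 1.00, 0.30, 0.31),
    "transrate_optimal_score": (0.30, 0.00, 0.23, 0.66, 0.32, 0.14, 0.61, 0.13, 1.00, 0.57),
    "pct_bases_uncovered": (0.38, 0.00, 0.33, 0.67, 0.57, 0.11, 1.00, 0.48, 0.99, 0.79),
    "ambiguous_bases": (0.72, 0.00, 0.53, 0.78, 0.83, 1.00, 0.91, 0.94, 0.86, 0.71),
    "nucleotide_f1": (0.59, 0.08, 0.77, 0.89, 0.71, 0.00, 0.86, 0.42, 0.97, 1.00),
    "contig_f1": (0.08, 0.09, 0.99, 1.00, 0.05, 0.00, 0.08, 0.11, 0.07, 0.06),
    "kc_score": (0.87, 0.00, 1.00, 0.42, 0.51, 0.40, 0.14, 0.58, 0.47, 0.60),
    "rsem_eval": (0.98, 0.45, 1.00, 0.72, 0.85, 0.62, 0.00, 0.73, 0.42, 0.91),
    "complete_buscos": (0.96, 0.79, 1.00, 0.39, 0.92, 0.13, 0.00, 0.70, 0.39, 0.58),
    "missing_buscos": (0.99, 0.93, 1.00, 0.83, 0.98, 0.00, 0.63, 0.84, 0.78, 0.92),
}

# printed per-assembler metric scores (last table row), same assembler order
TABLE2_MS = (12.38, 6.31, 14.24, 11.92, 11.13, 6.59, 8.61, 10.3, 11.47, 12.03)
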