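dataset	assembler	metric	value
hsa	Trinity	overall_mapping_rate	91.9
hsa	Oases	overall_mapping_rate	88.04
hsa	Trans-ABySS	overall_mapping_rate	98.34
hsa	SOAPdenovo-Trans	overall_mapping_rate	89.93
hsa	Bridger	overall_mapping_rate	86.83
hsa	BinPacker	overall_mapping_rate	72.6
hsa	IDBA-Tran	overall_mapping_rate	64.61
hsa	Shannon	overall_mapping_rate	84.27
hsa	SPAdes-sc	overall_mapping_rate	92.04
hsa	SPAdes-rna	overall_mapping_rate	95.95
hsa	Trinity	transcripts_ge_1000nt	64061
hsa	Oases	transcripts_ge_1000nt	207474
hsa	Trans-ABySS	transcripts_ge_1000nt	59779
hsa	SOAPdenovo-Trans	transcripts_ge_1000nt	27529
hsa	Bridger	transcripts_ge_1000nt	43201
hsa	BinPacker	transcripts_ge_1000nt	22611
hsa	IDBA-Tran	transcripts_ge_1000nt	23516
hsa	Shannon	transcripts_ge_1000nt	31328
hsa	SPAdes-sc	transcripts_ge_1000nt	31039
hsa	SPAdes-rna	transcripts_ge_1000nt	49860
hsa	Trinity	misassemblies	3378
hsa	Oases	misassemblies	216127
hsa	Trans-ABySS	misassemblies	2743
hsa	SOAPdenovo-Trans	misassemblies	279
hsa	Bridger	misassemblies	7329
hsa	BinPacker	misassemblies	5603
hsa	IDBA-Tran	misassemblies	302
hsa	Shannon	misassemblies	2837
hsa	SPAdes-sc	misassemblies	2022
hsa	SPAdes-rna	misassemblies	5126
hsa	Trinity	mismatches_per_transcript	1.38
hsa	Oases	mismatches_per_transcript	1.25
hsa	Trans-ABySS	mismatches_per_transcript	0.57
hsa	SOAPdenovo-Trans	mismatches_per_transcript	0.27
hsa	Bridger	mismatches_per_transcript	1.44
hsa	BinPacker	mismatches_per_transcript	4.63
hsa	IDBA-Tran	mismatches_per_transcript	0.67
hsa	Shannon	mismatches_per_transcript	1.26
hsa	SPAdes-sc	mismatches_per_transcript	0.8
hsa	SPAdes-rna	mismatches_per_transcript	1.25
hsa	Trinity	avg_alignment_length	795.23
hsa	Oases	avg_alignment_length	343.48
hsa	Trans-ABySS	avg_alignment_length	246.85
hsa	SOAPdenovo-Trans	avg_alignment_length	218
hsa	Bridger	avg_alignment_length	654.41
hsa	BinPacker	avg_alignment_length	2335.73
hsa	IDBA-Tran	avg_alignment_length	487.11
hsa	Shannon	avg_alignment_length	711.83
hsa	SPAdes-sc	avg_alignment_length	410.22
hsa	SPAdes-rna	avg_alignment_length	412.24
hsa	Trinity	pct95_assembled_isoforms	6788
hsa	Oases	pct95_assembled_isoforms	868
hsa	Trans-ABySS	pct95_assembled_isoforms	6824
hsa	SOAPdenovo-Trans	pct95_assembled_isoforms	2264
hsa	Bridger	pct95_assembled_isoforms	2105
hsa	BinPacker	pct95_assembled_isoforms	2824
hsa	IDBA-Tran	pct95_assembled_isoforms	709
hsa	Shannon	pct95_assembled_isoforms	242
hsa	SPAdes-sc	pct95_assembled_isoforms	1755
hsa	SPAdes-rna	pct95_assembled_isoforms	3253
hsa	Trinity	duplication_ratio	2.396
hsa	Oases	duplication_ratio	2.355
hsa	Trans-ABySS	duplication_ratio	1.743
hsa	SOAPdenovo-Trans	duplication_ratio	1.187
hsa	Bridger	duplication_ratio	1.708
hsa	BinPacker	duplication_ratio	2.389
hsa	IDBA-Tran	duplication_ratio	1.012
hsa	Shannon	duplication_ratio	1.53
hsa	SPAdes-sc	duplication_ratio	1.015
hsa	SPAdes-rna	duplication_ratio	1.192
hsa	Trinity	ex90n50	326
hsa	Oases	ex90n50	666
hsa	Trans-ABySS	ex90n50	441
hsa	SOAPdenovo-Trans	ex90n50	711
hsa	Bridger	ex90n50	1370
hsa	BinPacker	ex90n50	2381
hsa	IDBA-Tran	ex90n50	708
hsa	Shannon	ex90n50	1324
hsa	SPAdes-sc	ex90n50	1186
hsa	SPAdes-rna	ex90n50	782
hsa	Trinity	full_length_transcripts	8930
hsa	Oases	full_length_transcripts	8024
hsa	Trans-ABySS	full_length_transcripts	9110
hsa	SOAPdenovo-Trans	full_length_transcripts	6806
hsa	Bridger	full_length_transcripts	8440
hsa	BinPacker	full_length_transcripts	4456
hsa	IDBA-Tran	full_length_transcripts	2783
hsa	Shannon	full_length_transcripts	6758
hsa	SPAdes-sc	full_length_transcripts	5676
hsa	SPAdes-rna	full_length_transcripts	7155
hsa	Trinity	reference_coverage	0.23
hsa	Oases	reference_coverage	0.09
hsa	Trans-ABySS	reference_coverage	0.26
hsa	SOAPdenovo-Trans	reference_coverage	0.09
hsa	Bridger	reference_coverage	0.09
hsa	BinPacker	reference_coverage	0.07
hsa	IDBA-Tran	reference_coverage	0.08
hsa	Shannon	reference_coverage	0
hsa	SPAdes-sc	reference_coverage	0.08
hsa	SPAdes-rna	reference_coverage	0.11
hsa	Trinity	mean_orf_percentage	50.82
hsa	Oases	mean_orf_percentage	42.09
hsa	Trans-ABySS	mean_orf_percentage	51.92
hsa	SOAPdenovo-Trans	mean_orf_percentage	48.02
hsa	Bridger	mean_orf_percentage	45.1
hsa	BinPacker	mean_orf_percentage	42.57
hsa	IDBA-Tran	mean_orf_percentage	52.46
hsa	Shannon	mean_orf_percentage	55.7
hsa	SPAdes-sc	mean_orf_percentage	46.13
hsa	SPAdes-rna	mean_orf_percentage	46.25
hsa	Trinity	transrate_optimal_score	0.13
hsa	Oases	transrate_optimal_score	0.02
hsa	Trans-ABySS	transrate_optimal_score	0.11
hsa	SOAPdenovo-Trans	transrate_optimal_score	0.27
hsa	Bridger	transrate_optimal_score	0.14
hsa	BinPacker	transrate_optimal_score	0.07
hsa	IDBA-Tran	transrate_optimal_score	0.25
hsa	Shannon	transrate_optimal_score	0.07
hsa	SPAdes-sc	transrate_optimal_score	0.4
hsa	SPAdes-rna	transrate_optimal_score	0.23
hsa	Trinity	pct_bases_uncovered	0.59
hsa	Oases	pct_bases_uncovered	0.94
hsa	Trans-ABySS	pct_bases_uncovered	0.63
hsa	SOAPdenovo-Trans	pct_bases_uncovered	0.33
hsa	Bridger	pct_bases_uncovered	0.42
hsa	BinPacker	pct_bases_uncovered	0.84
hsa	IDBA-Tran	pct_bases_uncovered	0.02
hsa	Shannon	pct_bases_uncovered	0.5
hsa	SPAdes-sc	pct_bases_uncovered	0.03
hsa	SPAdes-rna	pct_bases_uncovered	0.21
hsa	Trinity	ambiguous_bases	286
hsa	Oases	ambiguous_bases	843
hsa	Trans-ABySS	ambiguous_bases	437
hsa	SOAPdenovo-Trans	ambiguous_bases	241
hsa	Bridger	ambiguous_bases	206
hsa	BinPacker	ambiguous_bases	72
hsa	IDBA-Tran	ambiguous_bases	138
hsa	Shannon	ambiguous_bases	117
hsa	SPAdes-sc	ambiguous_bases	177
hsa	SPAdes-rna	ambiguous_bases	294
hsa	Trinity	nucleotide_f1	0.43
hsa	Oases	nucleotide_f1	0.18
hsa	Trans-ABySS	nucleotide_f1	0.51
hsa	SOAPdenovo-Trans	nucleotide_f1	0.57
hsa	Bridger	nucleotide_f1	0.48
hsa	BinPacker	nucleotide_f1	0.15
hsa	IDBA-Tran	nucleotide_f1	0.55
hsa	Shannon	nucleotide_f1	0.35
hsa	SPAdes-sc	nucleotide_f1	0.61
hsa	SPAdes-rna	nucleotide_f1	0.62
hsa	Trinity	contig_f1	0.02
hsa	Oases	contig_f1	0.02
hsa	Trans-ABySS	contig_f1	0.2
hsa	SOAPdenovo-Trans	contig_f1	0.21
hsa	Bridger	contig_f1	0.01
hsa	BinPacker	contig_f1	0
hsa	IDBA-Tran	contig_f1	0.02
hsa	Shannon	contig_f1	0.02
hsa	SPAdes-sc	contig_f1	0.01
hsa	SPAdes-rna	contig_f1	0.01
hsa	Trinity	kc_score	0.51
hsa	Oases	kc_score	0.24
hsa	Trans-ABySS	kc_score	0.55
hsa	SOAPdenovo-Trans	kc_score	0.37
hsa	Bridger	kc_score	0.4
hsa	BinPacker	kc_score	0.37
hsa	IDBA-Tran	kc_score	0.29
hsa	Shannon	kc_score	0.42
hsa	SPAdes-sc	kc_score	0.39
hsa	SPAdes-rna	kc_score	0.43
hsa	Trinity	rsem_eval	-6.51
hsa	Oases	rsem_eval	-11.82
hsa	Trans-ABySS	rsem_eval	-6.26
hsa	SOAPdenovo-Trans	rsem_eval	-9.03
hsa	Bridger	rsem_eval	-7.72
hsa	BinPacker	rsem_eval	-10.03
hsa	IDBA-Tran	rsem_eval	-16.3
hsa	Shannon	rsem_eval	-8.96
hsa	SPAdes-sc	rsem_eval	-12.12
hsa	SPAdes-rna	rsem_eval	-7.16
hsa	Trinity	complete_buscos	4004
hsa	Oases	complete_buscos	3588
hsa	Trans-ABySS	complete_buscos	4106
hsa	SOAPdenovo-Trans	complete_buscos	2625
hsa	Bridger	complete_buscos	3909
hsa	BinPacker	complete_buscos	2009
hsa	IDBA-Tran	complete_buscos	1682
hsa	Shannon	complete_buscos	3385
hsa	SPAdes-sc	complete_buscos	2625
hsa	SPAdes-rna	complete_buscos	3089
hsa	Trinity	missing_buscos	1804
hsa	Oases	missing_buscos	1922
hsa	Trans-ABySS	missing_buscos	1770
hsa	SOAPdenovo-Trans	missing_buscos	2164
hsa	Bridger	missing_buscos	1812
hsa	BinPacker	missing_buscos	4078
hsa	IDBA-Tran	missing_buscos	2615
hsa	Shannon	missing_buscos	2133
hsa	SPAdes-sc	missing_buscos	2268
hsa	SPAdes-rna	missing_buscos	1949
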