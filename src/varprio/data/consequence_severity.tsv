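term	rank
transcript_ablation	1
splice_acceptor_variant	2
splice_donor_variant	3
stop_gained	4
frameshift_variant	5
stop_lost	6
start_lost	7
transcript_amplification	8
feature_elongation	9
feature_truncation	10
inframe_insertion	11
inframe_deletion	12
missense_variant	13
protein_altering_variant	14
splice_donor_5th_base_variant	15
splice_region_variant	16
splice_donor_region_variant	17
splice_polypyrimidine_tract_variant	18
incomplete_terminal_codon_variant	19
start_retained_variant	20
stop_retained_variant	21
synonymous_variant	22
coding_sequence_variant	23
mature_mirna_variant	24
5_prime_utr_variant	25
3_prime_utr_variant	26
non_coding_transcript_exon_variant	27
intron_variant	28
nmd_transcript_variant	29
non_coding_transcript_variant	30
coding_transcript_variant	31
upstream_gene_variant	32
genic_upstream_transcript_variant	33
downstream_gene_variant	34
genic_downstream_transcript_variant	35
tfbs_ablation	36
tfbs_amplification	37
tf_binding_site_variant	38
regulatory_region_ablation	39
regulatory_region_amplification	40
regulatory_region_variant	41
intergenic_variant	42
sequence_variant	43
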