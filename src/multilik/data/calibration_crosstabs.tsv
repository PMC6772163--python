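# Published cross-tabs of evidence categories for variants classified
# (Likely) Benign vs (Likely) Pathogenic by multifactorial likelihood analysis.
evidence_type	category	benign_count	pathogenic_count
splicing_allele_specific	none	11	0
splicing_allele_specific	partial	2	6
splicing_allele_specific	complete	1	5
splicing_all	none	46	0
splicing_all	any_impact	4	49
protein_function	none	56	0
protein_function	none_partial	3	0
protein_function	partial	1	0
protein_function	partial_complete	0	1
protein_function	complete	1	15
population_frequency	single_observation	59	8
population_frequency	mid	110	0
population_frequency	low	119	3
population_frequency	not_observed	155	78
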