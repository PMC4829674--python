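# Published pairwise p-values with the comparison each footnote defines.
# matching_variant: which summary t-test variant reproduces the printed p
# at its printed precision (pooled for a-d, welch for e; none of the two
# variants reproduces f, which is recorded for completeness only).
id	assay	cell_type	metric	group_a	group_b	p_printed	matching_variant
a	ALU	PBMC	pct_uCuC	inactive	control	0.03	pooled
b	ALU	PBMC	pct_uCuC	all_patients	control	0.03	pooled
c	ALU	NEUTROPHIL	pct_uCuC	inactive	control	0.002	pooled
d	ALU	NEUTROPHIL	pct_uCuC	all_patients	control	0.006	pooled
e	ALU	NEUTROPHIL	pct_partial	inactive	control	0.02	welch
f	ALU	NEUTROPHIL	pct_partial	all_patients	control	0.055	none
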