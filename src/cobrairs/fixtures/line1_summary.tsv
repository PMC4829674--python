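# Published LINE-1 methylation frequency summaries (mean/SD in percent).
# flag=suspected_typo: the PBMC control mCmC value repeats the %mC value
# (81.76 +/- 2.04) and is inconsistent with every other mCmC row (~68);
# rows carrying a flag are excluded from quantitative checks.
cell_type	group	n	metric	mean	sd	flag
PBMC	control	15	pct_mC	81.76	2.04
PBMC	control	15	pct_mCmC	81.76	2.04	suspected_typo
PBMC	control	15	pct_uCmC	9.62	3.39
PBMC	control	15	pct_mCuC	16.42	1.08
PBMC	control	15	pct_uCuC	5.22	1.07
PBMC	control	15	pct_partial	26.05	3.87
PBMC	active	12	pct_mC	81.61	1.63
PBMC	active	12	pct_mCmC	68.93	2.59
PBMC	active	12	pct_uCmC	8.29	1.92
PBMC	active	12	pct_mCuC	17.07	1.39
PBMC	active	12	pct_uCuC	5.71	0.80
PBMC	active	12	pct_partial	25.37	2.03
PBMC	inactive	17	pct_mC	81.15	1.18
PBMC	inactive	17	pct_mCmC	68.21	1.57
PBMC	inactive	17	pct_uCmC	9.80	1.97
PBMC	inactive	17	pct_mCuC	16.07	1.28
PBMC	inactive	17	pct_uCuC	5.92	1.59
PBMC	inactive	17	pct_partial	25.87	2.10
PBMC	all_patients	29	pct_mC	81.34	1.37
PBMC	all_patients	29	pct_mCmC	68.51	2.04
PBMC	all_patients	29	pct_uCmC	9.18	2.06
PBMC	all_patients	29	pct_mCuC	16.48	1.40
PBMC	all_patients	29	pct_uCuC	5.83	1.31
PBMC	all_patients	29	pct_partial	25.66	2.05
NEUTROPHIL	control	15	pct_mC	81.06	1.94
NEUTROPHIL	control	15	pct_mCmC	67.73	2.92
NEUTROPHIL	control	15	pct_uCmC	11.01	2.03
NEUTROPHIL	control	15	pct_mCuC	15.64	0.55
NEUTROPHIL	control	15	pct_uCuC	5.61	1.20
NEUTROPHIL	control	15	pct_partial	26.65	2.23
NEUTROPHIL	active	12	pct_mC	82.07	0.96
NEUTROPHIL	active	12	pct_mCmC	69.12	1.39
NEUTROPHIL	active	12	pct_uCmC	10.06	1.20
NEUTROPHIL	active	12	pct_mCuC	15.86	1.32
NEUTROPHIL	active	12	pct_uCuC	4.97	0.61
NEUTROPHIL	active	12	pct_partial	25.92	0.98
NEUTROPHIL	inactive	17	pct_mC	81.35	1.25
NEUTROPHIL	inactive	17	pct_mCmC	67.82	2.04
NEUTROPHIL	inactive	17	pct_uCmC	11.06	2.54
NEUTROPHIL	inactive	17	pct_mCuC	16.01	1.73
NEUTROPHIL	inactive	17	pct_uCuC	5.11	0.89
NEUTROPHIL	inactive	17	pct_partial	27.07	1.91
NEUTROPHIL	all_patients	29	pct_mC	81.65	1.18
NEUTROPHIL	all_patients	29	pct_mCmC	68.36	1.89
NEUTROPHIL	all_patients	29	pct_uCmC	10.64	2.12
NEUTROPHIL	all_patients	29	pct_mCuC	15.95	1.55
NEUTROPHIL	all_patients	29	pct_uCuC	5.05	0.78
NEUTROPHIL	all_patients	29	pct_partial	26.59	1.67
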