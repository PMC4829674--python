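# Published Alu methylation frequency summaries (mean/SD in percent).
cell_type	group	n	metric	mean	sd	flag
PBMC	control	15	pct_mC	42.14	2.07
PBMC	control	15	pct_mCmC	14.06	2.96
PBMC	control	15	pct_uCmC	31.90	2.28
PBMC	control	15	pct_mCuC	24.25	1.08
PBMC	control	15	pct_uCuC	29.79	2.08
PBMC	control	15	pct_partial	56.15	2.99
PBMC	active	12	pct_mC	41.57	0.92
PBMC	active	12	pct_mCmC	13.72	1.21
PBMC	active	12	pct_uCmC	31.25	0.93
PBMC	active	12	pct_mCuC	24.46	0.76
PBMC	active	12	pct_uCuC	30.58	1.13
PBMC	active	12	pct_partial	55.71	1.45
PBMC	inactive	17	pct_mC	41.50	1.03
PBMC	inactive	17	pct_mCmC	14.13	1.51
PBMC	inactive	17	pct_uCmC	30.62	0.94
PBMC	inactive	17	pct_mCuC	24.11	0.82
PBMC	inactive	17	pct_uCuC	31.13	1.11
PBMC	inactive	17	pct_partial	54.73	1.66
PBMC	all_patients	29	pct_mC	41.53	0.97
PBMC	all_patients	29	pct_mCmC	13.96	1.39
PBMC	all_patients	29	pct_uCmC	30.88	0.97
PBMC	all_patients	29	pct_mCuC	24.26	0.80
PBMC	all_patients	29	pct_uCuC	30.90	1.13
PBMC	all_patients	29	pct_partial	55.14	1.62
NEUTROPHIL	control	15	pct_mC	42.88	2.19
NEUTROPHIL	control	15	pct_mCmC	14.25	3.68
NEUTROPHIL	control	15	pct_uCmC	32.39	1.81
NEUTROPHIL	control	15	pct_mCuC	24.87	1.40
NEUTROPHIL	control	15	pct_uCuC	28.49	1.03
NEUTROPHIL	control	15	pct_partial	57.26	3.16
NEUTROPHIL	active	12	pct_mC	42.89	0.40
NEUTROPHIL	active	12	pct_mCmC	15.17	1.58
NEUTROPHIL	active	12	pct_uCmC	30.83	2.60
NEUTROPHIL	active	12	pct_mCuC	24.60	0.83
NEUTROPHIL	active	12	pct_uCuC	29.40	1.64
NEUTROPHIL	active	12	pct_partial	55.43	3.11
NEUTROPHIL	inactive	17	pct_mC	42.43	1.52
NEUTROPHIL	inactive	17	pct_mCmC	14.91	1.88
NEUTROPHIL	inactive	17	pct_uCmC	30.88	0.97
NEUTROPHIL	inactive	17	pct_mCuC	24.15	0.69
NEUTROPHIL	inactive	17	pct_uCuC	30.06	1.49
NEUTROPHIL	inactive	17	pct_partial	55.03	1.50
NEUTROPHIL	all_patients	29	pct_mC	42.62	1.20
NEUTROPHIL	all_patients	29	pct_mCmC	15.02	1.73
NEUTROPHIL	all_patients	29	pct_uCmC	30.86	1.79
NEUTROPHIL	all_patients	29	pct_mCuC	24.34	0.77
NEUTROPHIL	all_patients	29	pct_uCuC	29.78	1.56
NEUTROPHIL	all_patients	29	pct_partial	55.20	2.26
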