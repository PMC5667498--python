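locus	method	t_my	excluded	note
1p36.13	ltr_vs_ltr	14.1
1p36.13	ltr_vs_consensus	21.0
1p36.13	gag_vs_consensus	22.5
1p36.13	env_vs_consensus	31.9
1p22.2	env_vs_consensus	45.0
1q22	ltr_vs_ltr	14.7
1q22	ltr_vs_consensus	44.1
1q22	gag_vs_consensus	35.7
1q22	pol_vs_consensus	28.9
1q22	env_vs_consensus	32.7
6p22.1	ltr_vs_ltr	12.7
6p22.1	ltr_vs_consensus	36.5
6p22.1	gag_vs_consensus	43.0
6p22.1	pol_vs_consensus	18.9
6p22.1	env_vs_consensus	32.8
6p21.33a	ltr_vs_ltr	22.9
6p21.33a	ltr_vs_consensus	18.0
6p21.33a	gag_vs_consensus	25.2
6p21.33a	pol_vs_consensus	21.3
6p21.33a	env_vs_consensus	21.3
6p21.33b	ltr_vs_ltr	22.9
6p21.33b	ltr_vs_consensus	18.0
6p21.33b	gag_vs_consensus	25.2
6p21.33b	pol_vs_consensus	21.3
6p21.33b	env_vs_consensus	21.3
6q22.31	ltr_vs_ltr	17.2
6q22.31	ltr_vs_consensus	38.8
6q22.31	gag_vs_consensus	38.9
6q22.31	pol_vs_consensus	44.8
6q22.31	env_vs_consensus	35.1
19p13.2	gag_vs_consensus	165.7	yes	highly divergent gag; excluded from the final T
19p13.2	pol_vs_consensus	20.8
19q13.41	ltr_vs_consensus	46.0
19q13.41	gag_vs_consensus	37.4
19q13.41	pol_vs_consensus	27.2
19q13.41	env_vs_consensus	45.9
Yq11.221	ltr_vs_ltr	20.8
Yq11.221	ltr_vs_consensus	45.2
Yq11.221	gag_vs_consensus	41.5
Yq11.221	pol_vs_consensus	30.4
Yq11.221	env_vs_consensus	44.7
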