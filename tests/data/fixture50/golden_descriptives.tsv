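block	level	cases	cases_pct	noncases	noncases_pct
sex	male	1	25.0	3	27.3
sex	female	2	50.0	8	72.7
sex	unknown	1	25.0	0	0.0
age_group	<18	0	0.0	0	0.0
age_group	18-44	1	25.0	0	0.0
age_group	45-64	0	0.0	4	36.4
age_group	65-74	0	0.0	5	45.5
age_group	>75	2	50.0	1	9.1
age_group	unknown	1	25.0	1	9.1
country	DE	1	25.0	1	9.1
country	GB	1	25.0	1	9.1
country	US	1	25.0	7	63.6
country	Other countries	0	0.0	1	9.1
country	unknown	1	25.0	1	9.1
region	America	1	25.0	7	63.6
region	Europe	2	50.0	3	27.3
region	Asia	0	0.0	0	0.0
region	Oceania	0	0.0	0	0.0
region	Africa	0	0.0	0	0.0
region	unknown	1	25.0	1	9.1
serious_outcome	hospitalization	0	0.0	3	27.3
serious_outcome	disability	0	0.0	1	9.1
serious_outcome	life-threatening	0	0.0	0	0.0
serious_outcome	death	0	0.0	0	0.0
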