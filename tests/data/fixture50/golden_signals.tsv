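label	stratum	a	b	c	d	expected	ROR	ROR_low	ROR_high	IC	IC_low	IC_high	signal	criteria_detail	corrected
ACEI	all	4	11	8	27	3.6	1.23	0.31	4.93	0.13	-1.28	1.55	False	none	False
benazepril	all	0	1	12	37	0.24	1.0	0.04	26.15	-0.57			False	none	True
captopril	all	0	4	12	34	0.96	0.31	0.02	6.11	-1.55			False	none	True
enalapril	all	0	3	12	35	0.72	0.41	0.02	8.42	-1.29			False	none	True
fosinopril	all	0	1	12	37	0.24	1.0	0.04	26.15	-0.57			False	none	True
lisinopril	all	2	0	10	38	0.48	18.33	0.82	411.91	1.35	-0.65	3.35	False	none	True
moexipril	all	0	0	12	38	0.0	3.08	0.06	163.44				False	none	True
perindopril	all	0	1	12	37	0.24	1.0	0.04	26.15	-0.57			False	none	True
quinapril	all	0	0	12	38	0.0	3.08	0.06	163.44				False	none	True
ramipril	all	0	0	12	38	0.0	3.08	0.06	163.44				False	none	True
trandolapril	all	2	1	10	37	0.72	7.4	0.61	90.15	1.04	-0.96	3.03	False	none	False
ACEI	female	2	8	5	9	2.917	0.45	0.07	3.0	-0.45	-2.45	1.55	False	none	False
benazepril	female	0	1	7	16	0.292	0.73	0.03	20.18	-0.66			False	none	True
captopril	female	0	3	7	14	0.875	0.28	0.01	6.08	-1.46			False	none	True
enalapril	female	0	3	7	14	0.875	0.28	0.01	6.08	-1.46			False	none	True
fosinopril	female	0	0	7	17	0.0	2.33	0.04	128.96				False	none	True
lisinopril	female	1	0	6	17	0.292	8.08	0.29	224.49	0.92	-1.91	3.75	False	none	True
moexipril	female	0	0	7	17	0.0	2.33	0.04	128.96				False	none	True
perindopril	female	0	1	7	16	0.292	0.73	0.03	20.18	-0.66			False	none	True
quinapril	female	0	0	7	17	0.0	2.33	0.04	128.96				False	none	True
ramipril	female	0	0	7	17	0.0	2.33	0.04	128.96				False	none	True
trandolapril	female	1	0	6	17	0.292	8.08	0.29	224.49	0.92	-1.91	3.75	False	none	True
ACEI	male	1	3	0	18	0.182	15.86	0.53	474.38	1.14	-1.69	3.97	False	none	True
benazepril	male	0	0	1	21	0.0	14.33	0.2	1009.94				False	none	True
captopril	male	0	1	1	20	0.045	4.56	0.12	167.47	-0.13			False	none	True
enalapril	male	0	0	1	21	0.0	14.33	0.2	1009.94				False	none	True
fosinopril	male	0	1	1	20	0.045	4.56	0.12	167.47	-0.13			False	none	True
lisinopril	male	1	0	0	21	0.045	129.0	1.83	9089.42	1.46	-1.37	4.29	False	none	True
moexipril	male	0	0	1	21	0.0	14.33	0.2	1009.94				False	none	True
perindopril	male	0	0	1	21	0.0	14.33	0.2	1009.94				False	none	True
quinapril	male	0	0	1	21	0.0	14.33	0.2	1009.94				False	none	True
ramipril	male	0	0	1	21	0.0	14.33	0.2	1009.94				False	none	True
trandolapril	male	0	1	1	20	0.045	4.56	0.12	167.47	-0.13			False	none	True
ACEI	non_europe	2	8	8	26	2.273	0.81	0.14	4.63	-0.15	-2.15	1.85	False	none	False
benazepril	non_europe	0	1	10	33	0.227	1.06	0.04	28.12	-0.54			False	none	True
captopril	non_europe	0	3	10	31	0.682	0.43	0.02	9.0	-1.24			False	none	True
enalapril	non_europe	0	2	10	32	0.455	0.62	0.03	13.95	-0.93			False	none	True
fosinopril	non_europe	0	1	10	33	0.227	1.06	0.04	28.12	-0.54			False	none	True
lisinopril	non_europe	1	0	9	34	0.227	10.89	0.41	289.59	1.04	-1.78	3.87	False	none	True
moexipril	non_europe	0	0	10	34	0.0	3.29	0.06	175.9				False	none	True
perindopril	non_europe	0	1	10	33	0.227	1.06	0.04	28.12	-0.54			False	none	True
quinapril	non_europe	0	0	10	34	0.0	3.29	0.06	175.9				False	none	True
ramipril	non_europe	0	0	10	34	0.0	3.29	0.06	175.9				False	none	True
trandolapril	non_europe	1	0	9	34	0.227	10.89	0.41	289.59	1.04	-1.78	3.87	False	none	True
ACEI	excl_nsclc	4	11	7	28	3.3	1.45	0.35	5.97	0.24	-1.17	1.66	False	none	False
benazepril	excl_nsclc	0	1	11	38	0.22	1.12	0.04	29.29	-0.53			False	none	True
captopril	excl_nsclc	0	4	11	35	0.88	0.34	0.02	6.86	-1.46			False	none	True
enalapril	excl_nsclc	0	3	11	36	0.66	0.45	0.02	9.44	-1.21			False	none	True
fosinopril	excl_nsclc	0	1	11	38	0.22	1.12	0.04	29.29	-0.53			False	none	True
lisinopril	excl_nsclc	2	0	9	39	0.44	20.79	0.92	469.8	1.41	-0.59	3.41	False	none	True
moexipril	excl_nsclc	0	0	11	39	0.0	3.43	0.06	182.82				False	none	True
perindopril	excl_nsclc	0	1	11	38	0.22	1.12	0.04	29.29	-0.53			False	none	True
quinapril	excl_nsclc	0	0	11	39	0.0	3.43	0.06	182.82				False	none	True
ramipril	excl_nsclc	0	0	11	39	0.0	3.43	0.06	182.82				False	none	True
trandolapril	excl_nsclc	2	1	9	38	0.66	8.44	0.69	103.7	1.11	-0.89	3.11	False	none	False
ACEI	diabetes	0	1	2	1	0.5	0.2	0.0	8.82	-1.0			False	none	True
benazepril	diabetes	0	0	2	2	0.0	1.0	0.01	73.26				False	none	True
captopril	diabetes	0	1	2	1	0.5	0.2	0.0	8.82	-1.0			False	none	True
enalapril	diabetes	0	0	2	2	0.0	1.0	0.01	73.26				False	none	True
fosinopril	diabetes	0	0	2	2	0.0	1.0	0.01	73.26				False	none	True
lisinopril	diabetes	0	0	2	2	0.0	1.0	0.01	73.26				False	none	True
moexipril	diabetes	0	0	2	2	0.0	1.0	0.01	73.26				False	none	True
perindopril	diabetes	0	0	2	2	0.0	1.0	0.01	73.26				False	none	True
quinapril	diabetes	0	0	2	2	0.0	1.0	0.01	73.26				False	none	True
ramipril	diabetes	0	0	2	2	0.0	1.0	0.01	73.26				False	none	True
trandolapril	diabetes	0	0	2	2	0.0	1.0	0.01	73.26				False	none	True
ACEI	2004_2011	1	5	4	14	1.25	0.7	0.06	7.85	-0.22	-3.05	2.61	False	none	False
benazepril	2004_2011	0	1	5	18	0.208	1.12	0.04	31.61	-0.5			False	none	True
captopril	2004_2011	0	3	5	16	0.625	0.43	0.02	9.67	-1.17			False	none	True
enalapril	2004_2011	0	0	5	19	0.0	3.55	0.06	199.98				False	none	True
fosinopril	2004_2011	0	1	5	18	0.208	1.12	0.04	31.61	-0.5			False	none	True
lisinopril	2004_2011	0	0	5	19	0.0	3.55	0.06	199.98				False	none	True
moexipril	2004_2011	0	0	5	19	0.0	3.55	0.06	199.98				False	none	True
perindopril	2004_2011	0	0	5	19	0.0	3.55	0.06	199.98				False	none	True
quinapril	2004_2011	0	0	5	19	0.0	3.55	0.06	199.98				False	none	True
ramipril	2004_2011	0	0	5	19	0.0	3.55	0.06	199.98				False	none	True
trandolapril	2004_2011	1	0	4	19	0.208	13.0	0.45	374.53	1.08	-1.75	3.91	False	none	True
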