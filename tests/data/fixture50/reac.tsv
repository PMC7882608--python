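report_id	pt_code
R00000001	headache
R00000002	nausea
R00000003	oedema_peripheral
R00000004	syncope
R00000005	nausea
R00000006	nausea
R00000007	dizziness
R00000008	dizziness
R00000009	vomiting
R00000010	hypotension
R00000011	headache
R00000012	nausea
R00000013	headache
R00000014	productive_cough
R00000015	syncope
R00000016	fatigue
R00000017	productive_cough
R00000018	fatigue
R00000019	dyspnoea
R00000020	diarrhoea
R00000021	oedema_peripheral
R00000022	cough
R00000023	cardiac_failure
R00000024	cardiac_failure
R00000025	productive_cough
R00000026	rash
R00000027	syncope
R00000028	oedema_peripheral
R00000029	rash
R00000030	hypotension
R00000031	nausea
R00000032	fatigue
R00000033	cough
R00000034	dizziness
R00000035	dizziness
R00000036	productive_cough
R00000037	nausea
R00000038	migraine
R00000039	diarrhoea
R00000040	dyspnoea
R00000041	nausea
R00000042	cardiac_failure
R00000043	fatigue
R00000044	cough
R00000045	cardiac_failure
R00000046	diarrhoea
R00000047	dizziness
R00000048	headache
R00000049	cardiac_failure
R00000050	cardiac_failure
R00000001	bronchial_carcinoma
R00000004	lung_neoplasm_malignant
R00000005	lung_squamous_cell_carcinoma
R00000006	lung_neoplasm_malignant
R00000012	lung_neoplasm_malignant
R00000019	lung_adenocarcinoma
R00000023	non_small_cell_lung_cancer
R00000024	lung_neoplasm_malignant
R00000025	bronchioloalveolar_carcinoma
R00000032	small_cell_lung_cancer
R00000035	lung_adenocarcinoma
R00000038	small_cell_lung_cancer
R00000011	leukaemic_infiltration_pulmonary
R00000014	leukaemic_infiltration_pulmonary
R00000036	leukaemic_infiltration_pulmonary
R00000045	metastases_to_lung
R00000009	cough
R00000012	vomiting
R00000013	fatigue
R00000015	rash
R00000016	cough
R00000023	rash
R00000024	fatigue
R00000026	productive_cough
R00000029	nausea
R00000030	fatigue
R00000033	rash
R00000038	cardiac_failure
R00000039	dizziness
R00000041	diarrhoea
R00000044	hypotension
R00000046	cough
R00000048	cardiac_failure
D00000002	vomiting
D00000003	cardiac_failure
D00000001	cardiac_failure
D00000001	metastases_to_lung
D00000002	cough
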