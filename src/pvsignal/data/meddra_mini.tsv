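pt_code	pt_name	hlt_code	hlt_name
lung_neoplasm_malignant	Lung neoplasm malignant	lower_respiratory_tract_neoplasms	Lower respiratory tract neoplasms
lung_adenocarcinoma	Lung adenocarcinoma	lower_respiratory_tract_neoplasms	Lower respiratory tract neoplasms
lung_squamous_cell_carcinoma	Lung squamous cell carcinoma	lower_respiratory_tract_neoplasms	Lower respiratory tract neoplasms
small_cell_lung_cancer	Small cell lung cancer	lower_respiratory_tract_neoplasms	Lower respiratory tract neoplasms
non_small_cell_lung_cancer	Non-small cell lung cancer	lower_respiratory_tract_neoplasms	Lower respiratory tract neoplasms
bronchial_carcinoma	Bronchial carcinoma	lower_respiratory_tract_neoplasms	Lower respiratory tract neoplasms
bronchioloalveolar_carcinoma	Bronchioloalveolar carcinoma	lower_respiratory_tract_neoplasms	Lower respiratory tract neoplasms
carcinoid_tumour_pulmonary	Carcinoid tumour pulmonary	lower_respiratory_tract_neoplasms	Lower respiratory tract neoplasms
leukaemic_infiltration_pulmonary	Leukaemic infiltration pulmonary	lower_respiratory_tract_neoplasms	Lower respiratory tract neoplasms
endobronchial_lipoma	Endobronchial lipoma	lower_respiratory_tract_neoplasms	Lower respiratory tract neoplasms
benign_respiratory_tract_neoplasm	Benign respiratory tract neoplasm	lower_respiratory_tract_neoplasms	Lower respiratory tract neoplasms
benign_lung_neoplasm	Benign lung neoplasm	lower_respiratory_tract_neoplasms	Lower respiratory tract neoplasms
metastases_to_lung	Metastases to lung	lower_respiratory_tract_neoplasms	Lower respiratory tract neoplasms
headache	Headache	headaches_nec	Headaches NEC
migraine	Migraine	headaches_nec	Headaches NEC
dizziness	Dizziness	neurological_signs_and_symptoms_nec	Neurological signs and symptoms NEC
syncope	Syncope	neurological_signs_and_symptoms_nec	Neurological signs and symptoms NEC
nausea	Nausea	gastrointestinal_nonspecific_symptoms	Gastrointestinal nonspecific symptoms
vomiting	Vomiting	gastrointestinal_nonspecific_symptoms	Gastrointestinal nonspecific symptoms
diarrhoea	Diarrhoea	gastrointestinal_nonspecific_symptoms	Gastrointestinal nonspecific symptoms
cough	Cough	coughing_and_associated_symptoms	Coughing and associated symptoms
productive_cough	Productive cough	coughing_and_associated_symptoms	Coughing and associated symptoms
dyspnoea	Dyspnoea	breathing_abnormalities	Breathing abnormalities
rash	Rash	rashes_eruptions_and_exanthems_nec	Rashes eruptions and exanthems NEC
fatigue	Fatigue	asthenic_conditions	Asthenic conditions
oedema_peripheral	Oedema peripheral	oedema_nec	Oedema NEC
hypotension	Hypotension	vascular_hypotensive_disorders	Vascular hypotensive disorders
hypertension	Hypertension	vascular_hypertensive_disorders	Vascular hypertensive disorders
essential_hypertension	Essential hypertension	vascular_hypertensive_disorders	Vascular hypertensive disorders
diabetes_mellitus	Diabetes mellitus	diabetes_mellitus_incl_subtypes	Diabetes mellitus (incl subtypes)
type_1_diabetes_mellitus	Type 1 diabetes mellitus	diabetes_mellitus_incl_subtypes	Diabetes mellitus (incl subtypes)
type_2_diabetes_mellitus	Type 2 diabetes mellitus	diabetes_mellitus_incl_subtypes	Diabetes mellitus (incl subtypes)
cardiac_failure	Cardiac failure	heart_failures_nec	Heart failures NEC
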