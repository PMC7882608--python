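synonym	generic	class
BENAZEPRIL	benazepril	ACEI
LOTENSIN	benazepril	ACEI
CAPTOPRIL	captopril	ACEI
CAPOTEN	captopril	ACEI
ENALAPRIL	enalapril	ACEI
ENALAPRIL MALEATE	enalapril	ACEI
VASOTEC	enalapril	ACEI
FOSINOPRIL	fosinopril	ACEI
MONOPRIL	fosinopril	ACEI
LISINOPRIL	lisinopril	ACEI
PRINIVIL	lisinopril	ACEI
ZESTRIL	lisinopril	ACEI
MOEXIPRIL	moexipril	ACEI
UNIVASC	moexipril	ACEI
PERINDOPRIL	perindopril	ACEI
ACEON	perindopril	ACEI
QUINAPRIL	quinapril	ACEI
ACCUPRIL	quinapril	ACEI
RAMIPRIL	ramipril	ACEI
ALTACE	ramipril	ACEI
TRANDOLAPRIL	trandolapril	ACEI
MAVIK	trandolapril	ACEI
IRBESARTAN	irbesartan	ARB
AVAPRO	irbesartan	ARB
LOSARTAN	losartan	ARB
COZAAR	losartan	ARB
HYDROCHLOROTHIAZIDE	hydrochlorothiazide	thiazide
HCTZ	hydrochlorothiazide	thiazide
MICROZIDE	hydrochlorothiazide	thiazide
CHLOROTHIAZIDE	chlorothiazide	thiazide
DIURIL	chlorothiazide	thiazide
BENDROFLUMETHIAZIDE	bendroflumethiazide	thiazide
METHYCLOTHIAZIDE	methyclothiazide	thiazide
INDAPAMIDE	indapamide	thiazide
METFORMIN	metformin	antidiabetic
GLUCOPHAGE	metformin	antidiabetic
GLIPIZIDE	glipizide	antidiabetic
GLUCOTROL	glipizide	antidiabetic
GLYBURIDE	glyburide	antidiabetic
INSULIN GLARGINE	insulin glargine	antidiabetic
LANTUS	insulin glargine	antidiabetic
SITAGLIPTIN	sitagliptin	antidiabetic
JANUVIA	sitagliptin	antidiabetic
ATORVASTATIN	atorvastatin	statin
LIPITOR	atorvastatin	statin
SIMVASTATIN	simvastatin	statin
ZOCOR	simvastatin	statin
OMEPRAZOLE	omeprazole	ppi
PRILOSEC	omeprazole	ppi
PANTOPRAZOLE	pantoprazole	ppi
PROTONIX	pantoprazole	ppi
PARACETAMOL	paracetamol	analgesic
ACETAMINOPHEN	paracetamol	analgesic
TYLENOL	paracetamol	analgesic
IBUPROFEN	ibuprofen	analgesic
ADVIL	ibuprofen	analgesic
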