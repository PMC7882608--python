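report_id	verbatim_name	role
R00000004	LISINOPRIL 5MG ORAL	suspect
R00000005	LISINOPRIL 25MG TABLET	suspect
R00000006	TRANDOLAPRIL	suspect
R00000007	CAPTOPRIL 25MG TABLET	suspect
R00000009	FOSINOPRIL	concomitant
R00000013	CAPTOPRIL 5MG ORAL	interacting
R00000017	ENALAPRIL 10MG	interacting
R00000018	TRANDOLAPRIL	interacting
R00000025	TRANDOLAPRIL 10MG	concomitant
R00000027	BENAZEPRIL 10MG	suspect
R00000030	PERINDOPRIL 10MG	suspect
R00000031	ENALAPRIL 10MG	suspect
R00000039	CAPTOPRIL 5MG ORAL	suspect
R00000040	ENALAPRIL 5MG ORAL	concomitant
R00000043	CAPTOPRIL 5MG ORAL	suspect
R00000009	IRBESARTAN 10MG	suspect
R00000020	IRBESARTAN 25MG TABLET	concomitant
R00000021	IRBESARTAN 5MG ORAL	suspect
R00000023	IRBESARTAN 25MG TABLET	suspect
R00000031	IRBESARTAN 5MG ORAL	suspect
R00000037	IRBESARTAN 10MG	suspect
R00000042	IRBESARTAN 25MG TABLET	suspect
R00000044	IRBESARTAN 10MG	concomitant
R00000037	PANTOPRAZOLE 5MG ORAL	suspect
R00000039	PANTOPRAZOLE 10MG	suspect
R00000050	PANTOPRAZOLE 10MG	suspect
R00000012	ATORVASTATIN 25MG TABLET	suspect
R00000013	ATORVASTATIN	suspect
R00000014	SIMVASTATIN	suspect
R00000026	SIMVASTATIN 5MG ORAL	concomitant
R00000039	SIMVASTATIN 10MG	interacting
R00000042	ATORVASTATIN 5MG ORAL	concomitant
R00000045	ATORVASTATIN 5MG ORAL	interacting
R00000004	HYDROCHLOROTHIAZIDE 5MG ORAL	suspect
R00000009	BENDROFLUMETHIAZIDE 25MG TABLET	concomitant
R00000013	CHLOROTHIAZIDE 10MG	suspect
R00000015	BENDROFLUMETHIAZIDE 5MG ORAL	suspect
R00000017	BENDROFLUMETHIAZIDE 10MG	interacting
R00000019	CHLOROTHIAZIDE 5MG ORAL	concomitant
R00000022	BENDROFLUMETHIAZIDE 25MG TABLET	concomitant
R00000023	CHLOROTHIAZIDE 25MG TABLET	suspect
R00000024	BENDROFLUMETHIAZIDE	concomitant
R00000029	HYDROCHLOROTHIAZIDE 5MG ORAL	concomitant
R00000035	BENDROFLUMETHIAZIDE 5MG ORAL	suspect
R00000037	CHLOROTHIAZIDE 5MG ORAL	suspect
R00000042	BENDROFLUMETHIAZIDE 10MG	suspect
R00000044	CHLOROTHIAZIDE 10MG	concomitant
R00000049	BENDROFLUMETHIAZIDE 25MG TABLET	suspect
R00000011	METFORMIN 25MG TABLET	concomitant
R00000013	INSULIN GLARGINE 5MG ORAL	suspect
R00000001	PARACETAMOL	suspect
R00000002	PARACETAMOL 5MG ORAL	interacting
R00000003	PARACETAMOL 5MG ORAL	suspect
R00000008	IBUPROFEN 5MG ORAL	suspect
R00000010	PARACETAMOL 10MG	concomitant
R00000016	PARACETAMOL 5MG ORAL	concomitant
R00000028	PARACETAMOL 25MG TABLET	suspect
R00000032	PARACETAMOL 10MG	suspect
R00000033	PARACETAMOL	concomitant
R00000034	PARACETAMOL 25MG TABLET	suspect
R00000036	PARACETAMOL	suspect
R00000038	PARACETAMOL	concomitant
R00000041	PARACETAMOL 25MG TABLET	suspect
R00000046	PARACETAMOL 10MG	concomitant
R00000047	IBUPROFEN	suspect
R00000048	PARACETAMOL	interacting
D00000002	FOSINOPRIL	concomitant
D00000002	IRBESARTAN 10MG	suspect
D00000003	IRBESARTAN 25MG TABLET	suspect
D00000003	ATORVASTATIN 5MG ORAL	concomitant
D00000001	ATORVASTATIN 5MG ORAL	interacting
D00000002	BENDROFLUMETHIAZIDE 25MG TABLET	concomitant
D00000003	BENDROFLUMETHIAZIDE 10MG	suspect
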