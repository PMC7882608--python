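report_id	pt_code
R00000004	hypertension
R00000006	hypertension
R00000015	hypertension
R00000018	hypertension
R00000019	hypertension
R00000023	hypertension
R00000024	hypertension
R00000029	hypertension
R00000031	hypertension
R00000037	hypertension
R00000039	hypertension
R00000040	hypertension
R00000043	hypertension
R00000044	hypertension
R00000011	diabetes_mellitus
R00000013	diabetes_mellitus
R00000019	type_2_diabetes_mellitus
R00000035	type_2_diabetes_mellitus
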