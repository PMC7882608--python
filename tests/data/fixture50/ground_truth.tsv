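report_id	source_id	is_duplicate	event	diabetes	exposed_ACEI	exposed_irbesartan	exposed_ppi	exposed_statin	exposed_thiazide
R00000001	R00000001	False	True	False	False	False	False	False	False
R00000002	R00000002	False	False	False	False	False	False	False	False
R00000003	R00000003	False	False	False	False	False	False	False	False
R00000004	R00000004	False	True	False	True	False	False	False	True
R00000005	R00000005	False	True	False	True	False	False	False	False
R00000006	R00000006	False	True	False	True	False	False	False	False
R00000007	R00000007	False	False	False	True	False	False	False	False
R00000008	R00000008	False	False	False	False	False	False	False	False
R00000009	R00000009	False	False	False	True	True	False	False	True
R00000010	R00000010	False	False	False	False	False	False	False	False
R00000011	R00000011	False	False	True	False	False	False	False	False
R00000012	R00000012	False	True	False	False	False	False	True	False
R00000013	R00000013	False	False	True	True	False	False	True	True
R00000014	R00000014	False	False	False	False	False	False	True	False
R00000015	R00000015	False	False	False	False	False	False	False	True
R00000016	R00000016	False	False	False	False	False	False	False	False
R00000017	R00000017	False	False	False	True	False	False	False	True
R00000018	R00000018	False	False	False	True	False	False	False	False
R00000019	R00000019	False	True	True	False	False	False	False	True
R00000020	R00000020	False	False	False	False	True	False	False	False
R00000021	R00000021	False	False	False	False	True	False	False	False
R00000022	R00000022	False	False	False	False	False	False	False	True
R00000023	R00000023	False	True	False	False	True	False	False	True
R00000024	R00000024	False	True	False	False	False	False	False	True
R00000025	R00000025	False	True	False	True	False	False	False	False
R00000026	R00000026	False	False	False	False	False	False	True	False
R00000027	R00000027	False	False	False	True	False	False	False	False
R00000028	R00000028	False	False	False	False	False	False	False	False
R00000029	R00000029	False	False	False	False	False	False	False	True
R00000030	R00000030	False	False	False	True	False	False	False	False
R00000031	R00000031	False	False	False	True	True	False	False	False
R00000032	R00000032	False	True	False	False	False	False	False	False
R00000033	R00000033	False	False	False	False	False	False	False	False
R00000034	R00000034	False	False	False	False	False	False	False	False
R00000035	R00000035	False	True	True	False	False	False	False	True
R00000036	R00000036	False	False	False	False	False	False	False	False
R00000037	R00000037	False	False	False	False	True	True	False	True
R00000038	R00000038	False	True	False	False	False	False	False	False
R00000039	R00000039	False	False	False	True	False	True	True	False
R00000040	R00000040	False	False	False	True	False	False	False	False
R00000041	R00000041	False	False	False	False	False	False	False	False
R00000042	R00000042	False	False	False	False	True	False	True	True
R00000043	R00000043	False	False	False	True	False	False	False	False
R00000044	R00000044	False	False	False	False	True	False	False	True
R00000045	R00000045	False	False	False	False	False	False	True	False
R00000046	R00000046	False	False	False	False	False	False	False	False
R00000047	R00000047	False	False	False	False	False	False	False	False
R00000048	R00000048	False	False	False	False	False	False	False	False
R00000049	R00000049	False	False	False	False	False	False	False	True
R00000050	R00000050	False	False	False	False	False	True	False	False
D00000001	R00000045	True	False	False	False	False	False	True	False
D00000002	R00000009	True	False	False	True	True	False	False	True
D00000003	R00000042	True	False	False	False	True	False	True	True
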