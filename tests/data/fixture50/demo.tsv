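report_id	version	sex	age_group	country	receipt_year	receipt_quarter	outcomes
R00000001	1	female	45-64	unknown	2009	3	hospitalization
R00000002	1	male	<18	GB	2017	1	
R00000003	1	female	unknown	US	2004	2	hospitalization
R00000004	1	female	>75	unknown	2018	2	
R00000005	1	male	>75	DE	2012	4	
R00000006	1	unknown	unknown	GB	2006	4	
R00000007	1	female	65-74	US	2008	1	hospitalization
R00000008	1	female	65-74	US	2012	4	death
R00000009	1	male	45-64	US	2009	1	
R00000010	1	male	45-64	unknown	2005	3	
R00000011	1	male	>75	US	2014	4	
R00000012	1	unknown	65-74	US	2014	4	death
R00000013	1	female	65-74	US	2005	1	hospitalization
R00000014	1	female	unknown	US	2008	4	hospitalization
R00000015	1	male	>75	US	2007	1	
R00000016	1	male	65-74	CN	2014	3	
R00000017	1	female	65-74	DE	2015	2	
R00000018	1	male	45-64	GB	2015	2	
R00000019	1	female	18-44	US	2019	1	life-threatening
R00000020	1	female	65-74	CA	2016	4	
R00000021	1	female	45-64	US	2009	2	
R00000022	1	male	65-74	CA	2005	3	
R00000023	1	unknown	unknown	US	2013	2	
R00000024	1	female	45-64	US	2018	2	
R00000025	1	female	18-44	US	2019	4	
R00000026	1	male	45-64	US	2007	1	disability
R00000027	1	female	45-64	US	2007	3	hospitalization
R00000028	1	male	>75	US	2004	3	hospitalization
R00000029	1	male	65-74	US	2006	2	hospitalization
R00000030	1	female	unknown	US	2012	2	
R00000031	1	female	>75	US	2012	1	
R00000032	1	unknown	65-74	unknown	2009	4	disability
R00000033	1	male	unknown	US	2008	4	
R00000034	1	male	45-64	US	2017	1	
R00000035	1	female	18-44	US	2011	1	
R00000036	1	male	45-64	US	2016	1	
R00000037	1	male	>75	unknown	2019	1	
R00000038	1	female	65-74	US	2009	4	
R00000039	1	male	45-64	FR	2007	4	
R00000040	1	female	65-74	US	2019	1	disability
R00000041	1	male	45-64	US	2014	3	
R00000042	1	female	>75	US	2008	1	hospitalization
R00000043	1	female	65-74	unknown	2013	2	
R00000044	1	male	65-74	US	2012	3	death
R00000045	1	female	45-64	US	2018	3	hospitalization
R00000046	1	female	>75	US	2008	4	
R00000047	1	male	45-64	US	2019	1	
R00000048	1	male	18-44	US	2018	1	
R00000049	1	female	45-64	US	2006	2	
R00000050	1	male	unknown	US	2006	2	
D00000001	1	female	45-64	US	2018	3	hospitalization
D00000002	1	male	45-64	US	2009	1	
D00000003	1	female	>75	US	2008	1	hospitalization
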