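# Retained anti-CRISPR candidate predictions for the 10 phage genomes.
# Scores and lengths transcribed from the published candidate table;
# query_cover values are synthetic placeholders >= 40% consistent with the
# stated retention criterion (covers were not printed).
genome_id	genus	family_id	protein_id	length_aa	score_a	score_b	homolog_id	query_cover	crispr_type
SeAO1	Kuttervirus	phrog_4097	Gp_007	56	0.62	-0.75	Acr00210	90	II-A
SeAO1	Kuttervirus	phrog_519	Gp_015	71	0.54	-2.08	Acr00037	90	I-D
SeAO1	Kuttervirus	phrog_5934	Gp_049	105	0.69	-4.64	Acr00193	90	II-A
SeAO1	Kuttervirus	phrog_3594	Gp_088	62	0.58	-3.57	Acr00054	90	I-D
SeEM1	Kuttervirus	phrog_4097	Gp_008	56	0.62	-0.75	Acr00210	90	II-A
SeEM1	Kuttervirus	phrog_3594	Gp_080	62	0.55	-2.90	Acr00212	90	II-A
SeEM2	Kuttervirus	phrog_4097	Gp_008	56	0.62	-0.75	Acr00210	90	II-A
SeEM2	Kuttervirus	phrog_519	GP_016	71	0.54	-2.08	Acr00037	90	I-D
SeEM4	Kuttervirus	phrog_4097	Gp_007	56	0.62	-0.75	Acr00210	90	II-A
SeEM4	Kuttervirus	phrog_519	Gp_015	71	0.54	-2.08	Acr00037	90	I-D
SeF3a	Kuttervirus	phrog_4097	Gp_008	56	0.62	-0.74	Acr00210	90	II-A
SeF3a	Kuttervirus	phrog_519	Gp_014	78	0.48	-1.17	Acr00037	90	I-D
SeF3a	Kuttervirus	phrog_3594	Gp_082	62	0.54	-2.77	Acr00212	90	II-A
SeF6a	Kuttervirus	phrog_4097	Gp_007	56	0.62	-0.74	Acr00210	90	II-A
SeF6a	Kuttervirus	phrog_5934	Gp_042	110	0.68	-3.85	Acr00211	90	II-A
SeF1	Jerseyvirus	phrog_13851	Gp_038	73	0.58	-4.11	Acr00209	90	II-A
SeF1	Jerseyvirus	phrog_18511	Gp_057	61	0.53	-1.96	Acr00311	90	V-A
SeF1	Jerseyvirus	phrog_6094	Gp_059	173	0.83	-3.57	Acr00061	90	I-E
SeF1	Jerseyvirus	phrog_2180	Gp_068	61	0.53	-4.87	Acr00128	90	I-F
SeF1	Jerseyvirus	phrog_1402	Gp_072	69	0.64	-3.92	Acr00070	90	I-F
SeF1	Jerseyvirus	singleton	Gp_073	62	0.70	-4.91	Acr00264	90	II-C
Se_F2	Chivirus	phrog_7965	Gp_051	120	0.84	-4.46	Acr00254	90	II-C
Se_F2	Chivirus	phrog_7734	Gp_052	111	0.54	-4.86	Acr00029	90	I-D
Se_F2	Chivirus	phrog_4445	Gp_057	85	0.77	-5.17	Acr00159	90	II-A
Se_F6b	Chivirus	phrog_7965	Gp_051	120	0.84	-4.21	Acr00275	90	II-C
Se_F6b	Chivirus	phrog_7734	Gp_052	111	0.53	-4.80	Acr00029	90	I-D
Se_F6b	Chivirus	phrog_4445	Gp_058	86	0.69	-4.94	Acr00198	90	II-A
Salfasec_13b	Lederbergvirus	phrog_11224	Gp_044	41	0.65	-4.56	Acr00064	90	I-E
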