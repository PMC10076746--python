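sample_id	region	cnv_type	gene_in_cnv	rna_in_cnv	zscore_chr	zscore_cnv	zscore_random1	zscore_random2	zscore_random3	log2fc_chr	log2fc_cnv	log2fc_random1	log2fc_random2	log2fc_random3
ASD0018	22q11.2	duplication	92	38	0.04	0.38	-0.1	0.145	0.095	-0.01	0.05	-0.015	0.015	0
ASD0027	7q11.23	duplication	35	16	0.095	3.745	0.345	0.245	-0.155	0	0.48	0.03	0.02	-0.01
ASD0060	2p16.3	deletion	1	0	-	-	-	-	-	-	-	-	-	-
ASD0144	16p13.11	duplication	42	17	-0.06	2.3	-0.29	-0.03	0.5	-0.015	0.38	-0.06	-0.01	0.06
ASD0203	15q11q13	duplication	122	3	0.06	2.56	0.8	-0.09	-0.85	0	0.38	0.1	-0.03	-0.12
ASD0214	3q26	deletion	15	1	0.03	-4.86	-1.26	1.74	0.69	-0.01	-0.41	-0.1	1.12	0.19
ASD0222	3q29	deletion	59	22	0.05	-5.025	0.205	-0.23	0.01	0	-0.775	0.01	-0.04	-0.005
ASD0330	15q11q13	duplication	130	5	-0.01	1.41	0.31	-0.23	0.46	-0.01	0.32	-0.06	-0.04	0.09
ASD0343	1q21.1	duplication	99	18	0.07	2.075	0.205	0.12	-0.065	0	0.385	0.02	0.005	-0.015
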