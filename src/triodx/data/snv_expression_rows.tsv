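sample_id	gene	expressed_in_blood	patient_level	cohort_mean_level
ASD0046	ASH1L	yes	1196.02	1206.834
ASD0061	EP300	yes	2520.55	2718.56
ASD0063	SCN2A	no	-	-
ASD0134	ADNP	yes	1663.37	1791.54
ASD0148	SHANK3	no	-	-
ASD0162	NF1	yes	534.96	615.19
ASD0219	PRKD1	no	-	-
ASD0221	SCN2A	no	-	-
ASD0294	PTEN	yes	3095.66	3948.45
ASD0326	SCN2A	no	-	-
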