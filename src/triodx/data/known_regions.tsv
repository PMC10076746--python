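name	chrom	start	end	syndrome	key_genes
22q11.2 proximal (A-D)	chr22	18910690	21463171	22q11.2 duplication (proximal, A-D) syndrome	TBX1
7q11.23 recurrent (WBS)	chr7	72688896	74173668	Williams-Beuren syndrome critical region	ELN
2p16.3 (NRXN1)	chr2	51046035	51696622	2p16.3 deletion syndrome	NRXN1
16p13.11 recurrent (BP2-BP3)	chr16	14901699	16492313	16p13.11 recurrent microduplication syndrome	MYH11
15q11q13 recurrent (BP2-BP3, Class 2)	chr15	23596697	28729564	15q11q13 recurrent (PWS/AS) region (BP2-BP3, Class 2)	UBE3A
3q26 (TBL1XR1)	chr3	176244949	178219435	3q26 deletion including TBL1XR1	TBL1XR1
3q29 recurrent	chr3	195740002	197962430	3q29 recurrent region (includes DLG1)	DLG1
1q21.1 recurrent (BP3-BP4, distal)	chr1	143691670	148830060	1q21.1 recurrent region (BP3-BP4, distal)	GJA5
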