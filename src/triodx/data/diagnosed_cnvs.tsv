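sample_id	sex	chrom	start	end	cnv_type	origin
ASD0018	male	chr22	18910690	21463171	duplication	de_novo
ASD0027	male	chr7	72688896	74173668	duplication	de_novo
ASD0060	male	chr2	51046035	51696622	deletion	paternal
ASD0144	male	chr16	14901699	16492313	duplication	maternal
ASD0203	female	chr15	23596697	28012138	duplication	maternal
ASD0214	female	chr3	176244949	178219435	deletion	de_novo
ASD0222	female	chr3	195740002	197962430	deletion	de_novo
ASD0330	male	chr15	23597027	28729564	duplication	de_novo
ASD0343	male	chr1	143691670	148830060	duplication	maternal
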