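sample_id	sex	gene	hgvs_c	hgvs_p	consequence	origin
ASD0046	female	ASH1L	c.8595delT	p.Gln2866fs	frameshift	de_novo
ASD0061	male	EP300	c.4242T>G	p.Tyr1414*	nonsense	de_novo
ASD0063	female	SCN2A	c.4550_4551del	p.Ala1517fs	frameshift	de_novo
ASD0134	male	ADNP	c.2156_2157insA	p.Tyr719*	nonsense	de_novo
ASD0148	female	SHANK3	c.4728_4740del	p.Leu1577fs	frameshift	de_novo
ASD0162	male	NF1	c.7395-2A>T		splice_acceptor	de_novo
ASD0219	female	PRKD1	c.41_71del	p.Leu14fs	frameshift	de_novo
ASD0221	male	SCN2A	c.605+1G>A		splice_donor	de_novo
ASD0294	male	PTEN	c.546dupA	p.Leu182fs	frameshift	de_novo
ASD0326	male	SCN2A	c.1570C>T	p.Arg524*	nonsense	de_novo
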