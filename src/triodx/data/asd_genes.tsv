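symbol	haploinsufficient
ASH1L	0
EP300	0
SCN2A	0
ADNP	0
SHANK3	1
NF1	1
PRKD1	0
PTEN	1
NRXN1	1
TBL1XR1	1
DLG1	1
ELN	0
MYH11	0
UBE3A	0
GJA5	0
TBX1	0
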