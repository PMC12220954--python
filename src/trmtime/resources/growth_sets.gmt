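proliferation	cell cycle / proliferation genes (editable default)	Mki67	Stmn1	Pclaf	Birc5	Top2a	Ccnb1	Cdk1	Tuba1b	Ube2c	Hmgb2	Ccna2	Cks1b
apoptosis	apoptosis genes (editable default)	Bax	Bcl2l11	Casp3	Casp8	Fas	Trp53	Bad	Bid	Apaf1	Cycs	Pmaip1	Bak1
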