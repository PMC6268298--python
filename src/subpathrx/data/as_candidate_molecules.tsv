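drugbank_id	molecule	p_value	n_overlap	type
DB07374	anisomycin	3.34E-11	8	experimental
DB02546	vorinostat	4.98E-08	5	approved
	quinostatin	6.28E-08	3
	lycorine	1.79E-06	4
	alexidine	3.47E-06	3
	ionomycin	3.47E-06	3
	ly-294002	3.47E-06	3
	trichostatin A	3.99E-06	5
	azacitidine	5.20E-06	3
DB06803	niclosamide	0.000754	2	approved
DB06803	parthenolide	0.003105	2	approved
DB01190	clindamycin	0.012813	1	approved
	pizotifen	0.025472	1
	thapsigargin	0.029659	1
DB00773	etoposide	0.046238	1	approved
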