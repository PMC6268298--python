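pathway_id	pathway_name	subpathway_id	p_value
path:00520	Amino sugar and nucleotide sugar metabolism	path:00520_1	0.003405
path:04662	B cell receptor signaling pathway	path:04662_2	0.008457
path:04110	Cell cycle	path:04110_16	0.009995
path:04110	Cell cycle	path:04110_21	0.001077
path:04110	Cell cycle	path:04110_26	0.000558
path:04110	Cell cycle	path:04110_3	0.002999
path:04110	Cell cycle	path:04110_4	0.000804
path:04062	Chemokine signaling pathway	path:04062_20	0.006018
path:04664	Fc epsilon RI signaling pathway	path:04664_10	0.006018
path:04664	Fc epsilon RI signaling pathway	path:04664_3	0.006018
path:04664	Fc epsilon RI signaling pathway	path:04664_5	0.003016
path:04664	Fc epsilon RI signaling pathway	path:04664_9	0.008457
path:04666	Fc gamma R-mediated phagocytosis	path:04666_3	0.008109
path:04666	Fc gamma R-mediated phagocytosis	path:04666_4	0.006903
path:04510	Focal adhesion	path:04510_26	0.002765
path:00052	Galactose metabolism	path:00052_7	0.001238
path:05160	Hepatitis C	path:05160_1	0.000137
path:05160	Hepatitis C	path:05160_4	2.81E-05
path:05160	Hepatitis C	path:05160_5	0.000643
path:04650	Natural killer cell mediated cytotoxicity	path:04650_3	0.004229
path:04722	Neurotrophin signaling pathway	path:04722_18	0.002847
path:04722	Neurotrophin signaling pathway	path:04722_21	0.001121
path:04722	Neurotrophin signaling pathway	path:04722_22	0.000804
path:04722	Neurotrophin signaling pathway	path:04722_23	0.009995
path:04722	Neurotrophin signaling pathway	path:04722_5	0.003948
path:04621	NOD-like receptor signaling pathway	path:04621_1	0.005705
path:05223	Non-small cell lung cancer	path:05223_6	0.008457
path:04330	Notch signaling pathway	path:04330_1	0.00757
path:05200	Pathways in cancer	path:05200_10	0.008404
path:05200	Pathways in cancer	path:05200_18	0.008457
path:05200	Pathways in cancer	path:05200_51	0.007638
path:05200	Pathways in cancer	path:05200_52	0.002695
path:04810	Regulation of actin cytoskeleton	path:04810_31	0.000643
path:05222	Small cell lung cancer	path:05222_1	0.001288
path:04620	Toll-like receptor signaling pathway	path:04620_6	0.004707
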