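component_id	name	kind	category	taste_class
No.1	Ethanol	VF	alcohol	
No.2	Phenethyl alcohol	VF	alcohol	
No.3	Ethyl acetate	VF	ester	
No.4	Ethyl isobutyrate	VF	ester	
No.5	Ethyl butyrate	VF	ester	
No.6	Ethyl 2-methylbutyrate	VF	ester	
No.7	Ethyl caproate/4-methyl-Pentanoic acid, ethyl ester	VF	ester	
No.8	Methyl benzoate	VF	ester	
No.9	2,6-Di-tert-butyl-4-methylphenol	VF	ester	
No.10	Methyl hexadecanoate	VF	ester	
No.11	Ethyl palmitate	VF	ester	
No.12	Octadecenoic acid methyl ester	VF	ester	
No.13	Methyl linoleate	VF	ester	
No.14	Ethyl oleate	VF	ester	
No.15	9,12-Octadecadienoic acid (Z, Z)-, ethyl ester	VF	ester	
No.16	(Z, Z, Z)-9,12,15-Octadecatrienoic acid, ethyl ester	VF	ester	
No.17	2,5-Dimethyl pyrazine	VF	pyrazine	
No.18	2,3,5-Trimethylpyrazine	VF	pyrazine	
No.19	3-ethyl-2,5-dimethyl-Pyrazine	VF	pyrazine	
No.20	Tetramethylpyrazine	VF	pyrazine	
No.21	3,5-diethyl-2-methyl-Pyrazine	VF	pyrazine	
No.22	Hexamethylcyclotrisiloxane	VF	alkane	
No.23	Octamethylcyclotetrasiloxane	VF	alkane	
No.24	Undecane	VF	alkane	
No.25	Isovaleraldehyde	VF	aldehyde	
No.26	Benzaldehyde	VF	aldehyde	
No.27	Phenylacetaldehyde	VF	aldehyde	
No.28	l-Caryophyllene	VF	aldehyde	
No.29	Guaiacol	VF	phenol	
No.30	2-Ethylphenol	VF	phenol	
No.31	Cocal	VF	phenol	
No.32	Butyric acid	VF	acid	
No.33	Isovaleric acid	VF	acid	
No.34	DL-2-Methylbutyric acid	VF	acid	
No.35	4-Methylvaleric acid	VF	acid	
No.36	Palmitic acid	VF	acid	
No.37	Linoleic acid	VF	acid	
No.38	Tetrahydrothiophene	VF	other	
No.39	2-Chloro-4-(4-methoxyphenyl)-6-(4-nitrophenyl) pyrimidine	VF	other	
No.40	1,3-diphenyl-1-(trimethylsilyioxy)-1-Heptene	VF	other	
No.41	alpha-ethylidene-Benzeneacetaldehyde	VF	other	
No.42	Ethyl 3-phenylpropionate	VF	other	
Glu	Glutamic acid	AA		umami
Asp	Aspartic acid	AA		umami
Ala	Alanine	AA		sweet
Gly	Glycine	AA		sweet
Ser	Serine	AA		sweet
Thr	Threonine	AA		sweet
Arg	Arginine	AA		bitter
His	Histidine	AA		bitter
Ile	Isoleucine	AA		bitter
Leu	Leucine	AA		bitter
Met	Methionine	AA		bitter
Trp	Tryptophan	AA		bitter
Tyr	Tyrosine	AA		bitter
Val	Valine	AA		bitter
Lys	Lysine	AA		unclassified
Phe	Phenylalanine	AA		unclassified
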