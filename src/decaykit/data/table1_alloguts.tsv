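locus	description	t_half_min
AT5G62410	SMC2 (STRUCTURAL MAINTENANCE OF CHROMOSOMES 2)	16.86
AT3G44260	CCR4-NOT transcription complex protein, putative	18.81
AT3G02550	LBD41 (LOB DOMAIN-CONTAINING PROTEIN 41)	19.45
AT3G10040	transcription factor	20.54
AT3G15210	ATERF-4 (ETHYLENE RESPONSIVE ELEMENT BINDING FACTOR 4)	21.72
AT1G18740	similar to unknown protein	21.87
AT2G28200	nucleic acid binding/transcription factor/zinc ion binding	23.28
AT2G44500	similar to unknown protein	23.38
AT1G28370	ATERF11/ERF11 (ERF domain protein 11)	24.06
AT4G11280	ACS6 (1-AMINOCYCLOPROPANE-1-CARBOXYLIC ACID (ACC) SYNTHASE 6)	24.15
AT4G15760	DL3920C, FCAALL.376, MO1, MONOOXYGENASE 1	24.71
AT5G63160	BTB and TAZ domain protein	25.00
AT2G22880	VQ motif-containing protein	25.08
AT2G31880	leucine-rich repeat transmembrane protein kinase, putative	25.08
AT1G02400	ATGA2OX6/DTA1 (GIBBERELLIN 2-OXIDASE 6)	25.14
AT4G27280	calcium-binding EF hand family protein	25.36
AT1G72520	lipoxygenase, putative	25.51
AT1G18300	ARABIDOPSIS THALIANA NUDIX HYDROLASE HOMOLOG 4, ATNUDT4,	25.56
AT5G22250	CCR4-NOT transcription complex protein, putative	25.70
AT3G15210	ATERF-4(ETHYLENE RESPONSIVE ELEMENT BINDING FACTOR 4)	26.04
AT5G17950	unknown protein	26.05
AT3G01830	calmodulin-related protein, putative	26.98
AT1G68840	RAV2 (REGULATOR OF THE ATPASE OF THE VACUOLAR MEMBRANE)	27.68
AT1G72950	disease resistance protein (TIR-NBS class), putative	27.98
AT2G28400	similar to unknown protein	28.02
AT2G41640	similar to unknown protein	28.34
AT1G72430	auxin-responsive protein-related	28.60
AT3G52450	U-box domain-containing protein	28.71
AT1G56510	disease resistance protein (TIR-NBS-LRR class), putative	28.72
AT3G19580	AZF2 (ARABIDOPSIS ZINC-FINGER PROTEIN 2)	28.96
AT1G17380	JAZ5/TIFY11A (JASMONATE-ZIM-DOMAIN PROTEIN 5)	29.00
AT2G01670	ATNUDT17 (Arabidopsis thaliana Nudix hydrolase homolog 17)	29.47
AT5G63790	ANAC102 (Arabidopsis NAC domain containing protein 102)	30.14
AT1G27730	STZ (SALT TOLERANCE ZINC FINGER)	30.20
AT1G66160	U-box domain-containing protein	30.21
AT4G18950	ankyrin protein kinase, putative	30.72
AT5G63450	CYP94B1 (cytochrome P450, family 94, subfamily B, polypeptide 1)	30.85
AT2G42760	similar to unnamed protein product [Vitis vinifera]	30.94
AT2G38470	WRKY33 (WRKY DNA-binding protein 33); transcription factor	31.65
AT1G76600	similar to unknown protein	31.94
AT4G33050	EDA39 (embryo sac development arrest 39); calmodulin binding	32.48
AT1G20510	OPCL1 (OPC-8:0 COA LIGASE1); 4-coumarate-CoA ligase	33.50
AT4G17500	ATERF-1 (ETHYLENE RESPONSIVE ELEMENT BINDING FACTOR 1)	34.02
AT5G11650	hydrolase, alpha/beta fold family protein	34.06
AT4G08170	inositol 1,3,4-trisphosphate 5/6-kinase family protein	34.12
AT1G27100	similar to unknown protein	34.26
AT5G13220	JAS1/JAZ10/TIFY9 (JASMONATE-ZIM-DOMAIN PROTEIN 10)	34.77
AT2G41410	calmodulin, putative	35.20
AT1G44350	ILL6 (IAA-leucine resistant (ILR)-like gene 6); metallopeptidase	35.55
AT4G24380	hydrolase, acting on ester bonds	36.05
AT1G09940	HEMA2; glutamyl-tRNA reductase	36.53
AT2G01180	ATPAP1 (PHOSPHATIDIC ACID PHOSPHATASE 1)	37.57
AT3G10930	similar to unknown protein [Arabidopsis thaliana] (TAIR:AT5G05300.1)	37.98
AT3G25780	AOC3 (ALLENE OXIDE CYCLASE 3)	38.15
AT1G16370	ATOCT6; carbohydrate transmembrane transporter	38.17
AT5G54170	similar to CP5 [Arabidopsis thaliana] (TAIR:AT1G64720.1)	38.17
AT5G05600	oxidoreductase, 2OG-Fe(II) oxygenase family protein	39.72
AT2G35460	harpin-induced family protein/HIN1 family protein	40.12
AT3G50950	disease resistance protein (CC-NBS-LRR class), putative	40.73
AT3G15500	ATNAC3 (ARABIDOPSIS NAC DOMAIN CONTAINING PROTEIN 55)	40.75
AT5G26030	FC1 (FERROCHELATASE 1); ferrochelatase	40.95
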