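no	peptide	-10lgP	m/z	z	mass	rt	ppm	area	sample	accessions	protein_source
1	LDTANEMNQLDLQFR	93.56	904.4365	2	1806.8571	34.18	8.3	1.0e6	pooled	OE9A085162P3:OE9A085162P1:OE9A085162P2	11S globulin subunit beta-like
2	VVLQDTSNNVNQLD	77.73	779.8878	2	1557.7634	24.96	5.9	3.44e5	pooled	OE9A032471P1:OE9A042009P1	legumin A-like
3	VVLQDTSNNVNQLDDIPRRFFLA	63.26	892.1344	3	2673.3875	48.98	5.2	ND	pooled	OE9A032471P1:OE9A042009P1	legumin A-like
4	AVVPIWLQPDTPAR	57.79	781.9397	2	1561.8616	38.09	9.6	4.39e5	pooled	OE9A001718P2:OE9A001718P1	apyrase-like
5	IFSGGESSGQPR	57.53	611.2961	2	1220.5785	22.47	6.8	1.24e5	pooled	OE9A032471P1:OE9A042009P1	legumin A-like
6	DTSNNVNQLDDIPRR	46.89	586.2892	3	1755.8500	26.25	5.1	1.54e5	pooled	OE9A032471P1:OE9A042009P1	legumin A-like
7	NCSTSIISG	39.01	441.2062	2	880.3961	35.88	9.5	3.49e7	pooled	OE9A087501P1	hypothetical predicted protein
8	VHVFRFDQNQDLLPIGN	34.71	671.3506	3	2011.0275	48.03	8.8	1.53e4	pooled	OE9A001718P2:OE9A001718P1	apyrase-like
9	LLLGAGCM(+15.99)	34.51	397.1985	2	792.3874	33.76	1.4	1.24e7	pooled	OE9A117792P1	zinc transporter 5-like
10	QDTSNNVNQLDDIPRR	33.36	628.9771	3	1883.9086	26.36	8.0	2.06e6	pooled	OE9A032471P1:OE9A042009P1	legumin A-like
11	FSASTEGS	32.74	393.1665	2	784.3239	25.27	0.5	9.63e5	pooled	OE9A013295P1:OE9A042038P1:OE9A062197P1	probable L-type lectin domain containing receptor kinase S.7
12	INTISGR	31.90	380.7197	2	759.4239	20.53	8.6	1.38e5	pooled	OE9A032471P1:OE9A042009P1	legumin A-like
13	LDGNSSAR	31.66	410.1964	2	818.3882	18.63	-4.9	1.41e5	pooled	OE9A106456P1	late blight resistance protein homolog R1A-10
14	VCGEAFGKA	31.36	441.2060	2	880.4113	33.38	-8.2	4.18e6	pooled	OE9A058866P1	translation initiation factor IF-2, chloroplastic
15	KGGGGGSGSAGGGGS	31.14	525.2275	2	1048.4534	35.95	-4.9	4.01e6	pooled	OE9A057915P1	mitogen-activated kinase 9-like, partial
16	SGPGNHEQ	30.94	413.1722	2	824.3413	30.38	-6.5	ND	pooled	OE9A054657P1:OE9A104108P1	hypothetical predicted protein
17	LGGGGSSGGAAC	30.30	447.1878	2	892.3708	20.67	-3.4	4.31e5	pooled	OE9A026632P1	VASP homolog
18	NALLCSNS	30.09	411.1950	2	820.3749	27.63	8.1	2.25e5	pooled	OE9A100476P1	transcription factor bHLH143-like
19	CPANGFY	29.54	386.1598	2	770.3057	26.19	6.7	ND	pooled	OE9A087887P1	basic endochitinase-like
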