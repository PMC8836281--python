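accession	protein_neg10lgP	n_peptides	cover_percent	area	protein_identification
OE9A032471P1	155.75	6	9	2.82e6	legumin A-like
OE9A042009P1	155.75	6	9	2.82e6	legumin A-like
OE9A085162P3	93.56	1	4	1.08e6	11S globulin subunit beta-like
OE9A085162P1	93.56	1	4	1.08e6	11S globulin subunit beta-like
OE9A085162P2	93.56	1	3	1.08e6	11S globulin subunit beta-like
OE9A001718P2	75.15	2	7	4.54e5	apyrase-like
OE9A001718P1	75.15	2	7	4.54e5	apyrase-like
OE9A057915P1	43.19	1	7	4.01e6	mitogen-activated kinase 9-like
OE9A117792P1	43.16	1	2	6.11e6	zinc transporter 5-like
OE9A087501P1	39.01	1	4	3.49e7	hypothetical predicted protein
OE9A013295P1	32.74	1	1	9.63e5	probable L-type lectin domain containing receptor kinase S.7
OE9A042038P1	32.74	1	1	9.63e5	probable L-type lectin domain containing receptor kinase S.7
OE9A062197P1	32.74	1	1	9.63e5	probable L-type lectin domain containing receptor kinase S.7
OE9A106456P1	31.66	1	1	7.40e4	late blight resistance protein homolog R1A-10
OE9A058866P1	31.36	1	1	4.18e6	translation initiation factor IF-2, chloroplastic
OE9A054657P1	30.94	1	3	0	hypothetical predicted protein
OE9A104108P1	30.94	1	2	0	hypothetical predicted protein
OE9A026632P1	30.3	1	4	4.31e5	VASP homolog
OE9A100476P1	30.09	1	2	2.25e5	hypothetical predicted protein (transcription factor bHLH143-like)
OE9A087887P1	29.54	1	3	0	basic endochitinase-like
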