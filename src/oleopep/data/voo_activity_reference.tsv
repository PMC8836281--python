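dataset	no	peptide	activity	count	A	B	consistent
db	1	LDTANEMNQLDLQFR	ACE_inhibitor	3	0.2000	7.24e-5	1
db	1	LDTANEMNQLDLQFR	DPP_IV_inhibitor	7	0.4667		1
db	1	LDTANEMNQLDLQFR	DPP_III_inhibitor	1	0.0667		1
db	1	LDTANEMNQLDLQFR	renin_inhibitor	1	0.0667		1
db	2	VVLQDTSNNVNQLD	ACE_inhibitor	2	0.1429		1
db	2	VVLQDTSNNVNQLD	other:glucose_uptake_stimulation	1	0.0714		1
db	2	VVLQDTSNNVNQLD	DPP_IV_inhibitor	9	0.6429	9.65e-4	1
db	3	VVLQDTSNNVNQLDDIPRRFFLA	ACE_inhibitor	9	0.3913	1.36e-2	1
db	3	VVLQDTSNNVNQLDDIPRRFFLA	other:ubiquitin_mediated_proteolysis_activator	1	0.0435		1
db	3	VVLQDTSNNVNQLDDIPRRFFLA	DPP_IV_inhibitor	10	0.2174		0
db	3	VVLQDTSNNVNQLDDIPRRFFLA	DPP_III_inhibitor	5	0.6087	8.62e-4	0
db	3	VVLQDTSNNVNQLDDIPRRFFLA	other:stimulation	1	0.0435		1
db	4	AVVPIWLQPDTPAR	ACE_inhibitor	10	0.7143	5.69e-2	1
db	4	AVVPIWLQPDTPAR	DPP_IV_inhibitor	10	0.7143	1.80e-3	1
db	5	IFSGGESSGQPR	ACE_inhibitor	9	0.7500	4.63e-2	1
db	5	IFSGGESSGQPR	antioxidant	1	0.0833		1
db	5	IFSGGESSGQPR	DPP_III_inhibitor	2	0.1667		1
db	5	IFSGGESSGQPR	DPP_IV_inhibitor	4	0.3333		1
db	5	IFSGGESSGQPR	other:neuropeptide	1	0.0833		1
db	6	DTSNNVNQLDDIPRR	ACE_inhibitor	3	0.2000	1.70e-2	1
db	6	DTSNNVNQLDDIPRR	DPP_IV_inhibitor	8	0.1333		0
db	6	DTSNNVNQLDDIPRR	DPP_III_inhibitor	2	0.5333	1.62e-4	0
db	7	NCSTSIISG	ACE_inhibitor	2	0.2222	2.75e-2	1
db	7	NCSTSIISG	DPP_IV_inhibitor	3	0.3333		1
db	7	NCSTSIISG	other:glucose_uptake_stimulation	1	0.1111		1
db	8	VHVFRFDQNQDLLPIGN	ACE_inhibitor	5	0.2941	8.20e-3	1
db	8	VHVFRFDQNQDLLPIGN	other:glucose_uptake_stimulation	1	0.0588		1
db	8	VHVFRFDQNQDLLPIGN	DPP_IV_inhibitor	11	0.6471	2.48e-5	1
db	8	VHVFRFDQNQDLLPIGN	DPP_III_inhibitor	2	0.1176		1
db	9	LLLGAGCM(+15.99)	ACE_inhibitor	3	0.3750	1.26e-4	1
db	9	LLLGAGCM(+15.99)	other:glucose_uptake_stimulation	2			1
db	9	LLLGAGCM(+15.99)	other:vasoactive_substance_release	1	0.3750		0
db	9	LLLGAGCM(+15.99)	DPP_IV_inhibitor	3	0.5000		0
db	10	QDTSNNVNQLDDIPRR	ACE_inhibitor	3	0.1875	1.59e-2	1
db	10	QDTSNNVNQLDDIPRR	DPP_IV_inhibitor	9	0.5625	1.52e-4	1
db	10	QDTSNNVNQLDDIPRR	DPP_III_inhibitor	2	0.1250		1
db	11	FSASTEGS	ACE_inhibitor	4	0.5000	3.11e-2	1
db	11	FSASTEGS	DPP_IV_inhibitor	3	0.3750		1
db	12	INTISGR	ACE_inhibitor	2	0.2857	6.14e-5	1
db	12	INTISGR	DPP_IV_inhibitor	3	0.4286		1
db	13	LDGNSSAR	ACE_inhibitor	2	0.2500	1.14e-2	1
db	14	VCGEAFGKA	ACE_inhibitor	7	0.7778	4.80e-3	1
db	14	VCGEAFGKA	other:alpha_glucosidase_inhibitor	1	0.1111	6.53e-6	1
db	14	VCGEAFGKA	DPP_IV_inhibitor	3	0.3333	1.78e-5	1
db	14	VCGEAFGKA	DPP_III_inhibitor	2	0.2222		1
db	15	KGGGGGSGSAGGGGS	ACE_inhibitor	13	0.8667	1.72e-4	1
db	15	KGGGGGSGSAGGGGS	DPP_IV_inhibitor	9	0.6000		1
db	16	SGPGNHEQ	ACE_inhibitor	4	0.5000	2.10e-3	1
db	16	SGPGNHEQ	other:antiamnestic	2	0.2500		1
db	16	SGPGNHEQ	other:antithrombotic	2	0.2500		1
db	16	SGPGNHEQ	other:stomach_mucosal_activity_regulation	2	0.2500		1
db	16	SGPGNHEQ	DPP_IV_inhibitor	4	0.5000	1.80e-3	1
db	17	LGGGGSSGGAAC	ACE_inhibitor	9	0.7500	2.63e-4	1
db	17	LGGGGSSGGAAC	antioxidant	1	0.0833		1
db	17	LGGGGSSGGAAC	DPP_IV_inhibitor	6	0.5000	8.87e-6	1
db	18	NALLCSNS	other:glucose_uptake_stimulation	1	0.1250		1
db	18	NALLCSNS	DPP_IV_inhibitor	3	0.3750	1.42e-6	1
db	19	CPANGFY	ACE_inhibitor	3	0.4286	5.90e-3	1
db	19	CPANGFY	DPP_IV_inhibitor	3	0.4286		1
db	19	CPANGFY	DPP_III_inhibitor	1	0.1429		1
denovo	1	CCYSVY	ACE_inhibitor	2	0.3333	4.39e-2	1
denovo	1	CCYSVY	antioxidant	1	0.1667		1
denovo	1	CCYSVY	DPP_III_inhibitor	3	0.1667		0
denovo	1	CCYSVY	DPP_IV_inhibitor	1	0.5000		0
denovo	2	DCHYFL	ACE_inhibitor	1	0.1667	6.38e-3	1
denovo	2	DCHYFL	other:anti_inflammatory	1	0.1667		1
denovo	2	DCHYFL	DPP_III_inhibitor	3	0.3333		0
denovo	2	DCHYFL	DPP_IV_inhibitor	2	0.5000	4.17e-4	0
denovo	3	LYPFAH	ACE_inhibitor	4	0.6667	3.47e-4	1
denovo	3	LYPFAH	other:alpha_glucosidase_inhibitor	1	0.1667	9.92e-5	1
denovo	3	LYPFAH	antioxidant	2	0.3333		1
denovo	3	LYPFAH	DPP_III_inhibitor	2	0.3333		1
denovo	3	LYPFAH	DPP_IV_inhibitor	4	0.6667	5.25e-5	1
denovo	3	LYPFAH	opioid	1	0.1667		1
denovo	3	LYPFAH	renin_inhibitor	1	0.1667		1
denovo	4	SVSKPGW	ACE_inhibitor	3	0.4286	1.12e-2	1
denovo	4	SVSKPGW	other:antiamnestic	1	0.1429		1
denovo	4	SVSKPGW	antioxidant	1	0.1429		1
denovo	4	SVSKPGW	other:antithrombotic	1	0.1429		1
denovo	4	SVSKPGW	other:stomach_activity_regulation	1	0.1429		1
denovo	4	SVSKPGW	DPP_IV_inhibitor	6	0.8571	5.62e-5	1
denovo	5	LHTVVH	antioxidant	2	0.3333		1
denovo	5	LHTVVH	DPP_IV_inhibitor	5	0.8333		1
denovo	6	NKLCCEH	ACE_inhibitor	3	0.4286	4.64e-3	1
denovo	6	NKLCCEH	DPP_IV_inhibitor	1	0.1429		1
denovo	7	DHHEEL	antioxidant	3	0.5000		1
denovo	7	DHHEEL	other:vasoactive_substance_release	1	0.1667		1
denovo	7	DHHEEL	DPP_IV_inhibitor	2	0.3333		1
denovo	8	LPCAAHR	ACE_inhibitor	2	0.2857	2.30e-4	1
denovo	8	LPCAAHR	antioxidant	1	0.1429		1
denovo	8	LPCAAHR	DPP_IV_inhibitor	4	0.5714	7.54e-5	1
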