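dataset	no	peptide	enzyme	fragments	rule_consistent	reported_annotations
db	1	LDTANEMNQLDLQFR	pepsin	L-DTANEMNQL-DL-QF-R	1	QF:renin_inhibitor;QF:DPP_IV_inhibitor
db	1	LDTANEMNQLDLQFR	chymotrypsin	L-DTAN-EM-N-QL-DL-QF-R	1	QF:renin_inhibitor;QF:DPP_IV_inhibitor;QL:DPP_IV_inhibitor
db	2	VVLQDTSNNVNQLD	pepsin	VVL-QDTSNNVNQL-D	1	VVL:ACE_inhibitor
db	2	VVLQDTSNNVNQLD	trypsin	VVL-QDTSNNVNQL-D	0	VVL:ACE_inhibitor
db	2	VVLQDTSNNVNQLD	chymotrypsin	VVL-QDTSN-N-VN-QL-D	1	VVL:ACE_inhibitor;QL:DPP_IV_inhibitor;VN:DPP_IV_inhibitor
db	3	VVLQDTSNNVNQLDDIPRRFFLA	pepsin	VVL-QDTSNNVNQL-DDIPRRF-F-L-A	1	VVL:ACE_inhibitor
db	3	VVLQDTSNNVNQLDDIPRRFFLA	chymotrypsin	VVL-QDTSN-N-VN-QL-DDIPRRF-F-L-A	1	VVL:ACE_inhibitor;QL:DPP_IV_inhibitor;VN:DPP_IV_inhibitor
db	5	IFSGGESSGQPR	pepsin	IF-SGGESSGQPR	1	IF:ACE_inhibitor
db	5	IFSGGESSGQPR	chymotrypsin	IF-SGGESSGQPR	1	IF:ACE_inhibitor
db	6	DTSNNVNQLDDIPRR	chymotrypsin	DTSN-N-VN-QL-DDIPRR	1	QL:DPP_IV_inhibitor;VN:DPP_IV_inhibitor
db	8	VHVFRFDQNQDLLPIGN	pepsin	VHVF-RF-DQNQDL-L-PIGN	1	RF:ACE_inhibitor;RF:DPP_III_inhibitor
db	8	VHVFRFDQNQDLLPIGN	chymotrypsin	VHVF-RF-DQNQDL-L-PIGN	0	RF:ACE_inhibitor;RF:DPP_III_inhibitor
db	10	QDTSNNVNQLDDIPRR	chymotrypsin	QDTSN-N-VN-QL-DDIPRR	1	QL:DPP_IV_inhibitor;VN:DPP_IV_inhibitor
db	11	FSASTEGS	chymotrypsin	F-SASTEGS	1
db	12	INTISGR	chymotrypsin	IN-TISGR	1	IN:DPP_IV_inhibitor
db	18	NALLCSNS	chymotrypsin	N-AL-L-CSN-S	1	AL:DPP_IV_inhibitor
db	19	CPANGFY	chymotrypsin	CPAN-GF-Y	1	GF:ACE_inhibitor;GF:DPP_IV_inhibitor;GF:DPP_III_inhibitor
denovo	1	CCYSVY	chymotrypsin	CCY-SVY	1	SVY:ACE_inhibitor
denovo	3	LYPFAH	chymotrypsin	L-YPF-AH	1	YPF:opioid
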