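dataset	no	peptide	ic50_uM	ic50_sd	teac	teac_sd
db	1	LDTANEMNQLDLQFR	ND	ND	ND	ND
db	2	VVLQDTSNNVNQLD	ND	ND	ND	ND
db	5	IFSGGESSGQPR	ND	ND	ND	ND
db	10	QDTSNNVNQLDDIPRR	ND	ND	ND	ND
db	14	VCGEAFGKA	57.2	4.31	0.79	0.02
db	18	NALLCSNS	0.98	0.04	0.95	0.03
db	19	CPANGFY	3.76	0.39	1.53	0.14
denovo	1	CCYSVY	25.6	0.41	3.20	0.19
denovo	2	DCHYFL	41.5	2.09	2.36	0.02
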