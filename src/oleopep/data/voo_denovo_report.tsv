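no	peptide	alc	m/z	z	mass	rt	area	ppm	local_confidence	sample
1	CCYSVY	95	369.1365	2	736.2560	24.36	5.77e5	3.2	92 97 99 93 92 98	pooled
2	DCHYFL	94	399.1715	2	796.3214	25.13	6.41e4	8.9	92 98 98 98 90 93	pooled
3	LYPFAH	94	374.1952	2	746.3751	19.07	3.59e5	1	99 99 99 85 89 93	pooled
4	SVSKPGW	92	380.7006	2	759.3915	14.03	1.85e5	-6.5	93 97 99 99 89 78 93	pooled
5	LHTVVH	91	353.2084	2	704.3970	26.06	8.67e4	7.6	99 93 93 92 85 87	pooled
6	NKLCCEH	91	423.6815	2	845.3524	29.15	ND	-4.7	84 95 98 94 86 94 89	pooled
7	DHHEEL	91	390.1661	2	778.3246	36.35	7.71e4	-8.9	89 91 97 91 92 85	pooled
8	LPCAAHR	90	384.2062	2	766.3908	19.09	2.70e5	9.2	98 79 79 89 97 96 95	pooled
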