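fragment	activity	ec50_um	source
VY	ACE_inhibitor	7.1	reported IC50
SVY	ACE_inhibitor	8.1	reported IC50
KA	ACE_inhibitor	31.5	reported IC50
FL	ACE_inhibitor	15.8	reported IC50
IPP	ACE_inhibitor	5	reported IC50 (dairy reference peptide)
VPP	ACE_inhibitor	9	reported IC50 (dairy reference peptide)
FY	ACE_inhibitor	22.125	reported IC50 range 1.65-42.6 uM; midpoint stored
GF	ACE_inhibitor		digestion-fragment annotation
QF	ACE_inhibitor		digestion-fragment annotation
IF	ACE_inhibitor		digestion-fragment annotation
RF	ACE_inhibitor		digestion-fragment annotation
VVL	ACE_inhibitor		digestion-fragment annotation
QF	renin_inhibitor		digestion-fragment annotation
QF	DPP_IV_inhibitor		digestion-fragment annotation
QL	DPP_IV_inhibitor		digestion-fragment annotation
VN	DPP_IV_inhibitor		digestion-fragment annotation
IN	DPP_IV_inhibitor		digestion-fragment annotation
AL	DPP_IV_inhibitor		digestion-fragment annotation
GF	DPP_IV_inhibitor		digestion-fragment annotation
RF	DPP_III_inhibitor		digestion-fragment annotation
GF	DPP_III_inhibitor		digestion-fragment annotation
YPF	opioid		digestion-fragment annotation
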