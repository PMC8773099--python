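symbol_a	symbol_b
IQSEC1	ARF6
PSD3	ARF6
PSD3	DNM2
BTBD7	DNM2
GLIS3	CTNNB1
LRBA	CTNNB1
LRBA	ARF6
GLIS3	GLI1
GLI1	SUFU
WASHC3	WASHC2
WASHC2	FAM21
SLC37A2	SLC37A4
ACTN4	ACTB
ACTB	MYH9
TP53	MDM2
MDM2	MDM4
EGFR	GRB2
GRB2	SOS1
KRAS	RAF1
CNR1	GNAI1
PRDM11	EHMT2
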