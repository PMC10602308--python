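# Curated demonstration network: the AKT arm (PDK1/SRC/MAPK14 -> AKT ->
# BAD/EZR) and the CDK1 arm (SRC/CHEK1/CDK7 -> CDK1 -> JUN/RPS6KB1/ESR1,
# CHEK1 -| TP53). Sites without a literature-stated position in this curation
# (IRS1 S636, ESR1 S118, CDK7->CDK1 T161) are synthetic placeholders.
kinase	substrate	site	effect
PDK1	AKT	S473	activation
PDK1	AKT	T308	activation
SRC	AKT	Y326	activation
MAPK14	AKT	S473	activation
AKT	BAD	S75	inhibition
AKT	EZR	T567	activation
SRC	CDK1	Y15	activation
CHEK1	CDK1	Y15	activation
CDK7	CDK1	T161	activation
CDK1	JUN	S73	activation
PIK3CA	RPS6KB1	T252	activation
PDK1	RPS6KB1	T252	activation
CDK1	RPS6KB1	S447	activation
RPS6KB1	IRS1	S636	inhibition
CDK1	ESR1	S118	activation
SRC	ESR1	S118	activation
CHEK1	TP53	S37	inhibition
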