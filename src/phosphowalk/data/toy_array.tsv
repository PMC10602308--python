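# 12-probe toy array (KAM-1325 rules): three probes trip the low-signal
# filter, two the relative-error filter, one the total-error filter.
probe_id	target	site	treated_signal	treated_error	control_signal	control_error
p01	AKT	S473	5000	100	4000	100
p02	MAPK1	T185	999	10	1500	10
p03	SRC	Y419	1500	10	800	10
p04	JUN	S73	1200	300	1000	0
p05	TP53	S37	1000	50	1000	50
p06	EZR	T567	2000	0	1000	0
p07	BAD	S75	800	5	1600	5
p08	CDK1	Y15	1600	0	2000	0
p09	RPS6KB1	T252	3000	100	2500	200
p10	CHEK1	S345	2400	120	1800	100
p11	ESR1	S118	1010	0	1000	0
p12	GSK3B	S9	1000	0	1000	0
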