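# Synthetic sign-consistent measurements for the demonstration network:
# positive CFC on the AKT arm, negative CFC on the CDK1 arm. Signals sit well
# above the KAM-1325 low-signal cutoff with small errors so every probe
# survives preprocessing. IRS1 S636 is deliberately unmeasured (single-path
# imputation exercises it).
probe_id	target	site	treated_signal	treated_error	control_signal	control_error
d01	AKT	S473	5000	100	4000	100
d02	AKT	T308	4800	100	4000	100
d03	AKT	Y326	4720	100	4000	100
d04	BAD	S75	4600	100	4000	100
d05	EZR	T567	2300	40	2000	40
d06	CDK1	Y15	3200	80	4000	80
d07	CDK1	T161	3520	80	4000	80
d08	JUN	S73	3280	80	4000	80
d09	RPS6KB1	T252	3600	60	4000	60
d10	RPS6KB1	S447	3440	60	4000	60
d11	TP53	S37	3360	80	4000	80
d12	ESR1	S118	3680	50	4000	50
d13	AKT	pan	5200	100	4000	100
d14	CDK1	pan	3400	80	4000	80
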