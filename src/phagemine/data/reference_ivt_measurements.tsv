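enzyme	template	promoter	ph	yield_mg_per_ml	integrity_pct	dsrna_pct
T7	Apt	TAATACGACTCACTATAGGGAGA	7.5	4.1	n/a	n/a
T7	GFP	TAATACGACTCACTATAGGGAGA	7.5	12.7	91.2	0.12
T7	FLuc	TAATACGACTCACTATAGGGAGA	7.5	10.9	98.5	0.51
T7	Cas9	TAATACGACTCACTATAGGGAGA	7.5	7.4	57.2	0.16
1575	Apt	TAATTAACCCACACTATAGGGACA	6.5	7.3	n/a	n/a
1575	GFP	TAATTAACCCACACTATAGGGACA	6.5	5.9	60.8	0.001
1575	FLuc	TAATTAACCCACACTATAGGGACA	6.5	1.0	18.1	0.007
1575	Cas9	TAATTAACCCACACTATAGGGACA	6.5	3.0	7.4	0.001
2049	Apt	TATTTACTGGACACTATAGGAGGA	6.5	1.6	n/a	n/a
2049	GFP	TATTTACTGGACACTATAGGAGGA	6.5	0.4	95.1	0.02
2049	FLuc	TATTTACTGGACACTATAGGAGGA	6.5	0.31	51.7	0.05
2049	Cas9	TATTTACTGGACACTATAGGAGGA	6.5	0.24	49.5	0.04
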