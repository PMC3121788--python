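label	time_min	pct_attached	sd	n
P0	0	100.0		4
P0	5	55.9		4
P0	15	24.5		4
P0	30	17.6		4
P0	60	8.8		4
P7	0	100.0		5
P7	5	49.2		5
P7	15	24.3		5
P7	30	20.5		5
P7	60	17.4		5
P80	0	100.0		5
P80	5	66.4		5
P80	15	37.7		5
P80	30	25.0		5
P80	60	17.4		5
P540	0	100.0		4
P540	5	76.5		4
P540	15	57.0		4
P540	30	46.1		4
P540	60	26.4		4
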