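age	mean_kbp	sd_kbp	n
P0	42.0	4.02	50
P7	36.0	3.05	50
P80	44.0	4.6	50
P540	40.6	5.9	50
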