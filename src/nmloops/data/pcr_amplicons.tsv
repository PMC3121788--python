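name	length_bp	chromosome_label	expressed
NFM	254	15p12	True
NFL	249	14	True
MBP	158	18q11-q13	False
GFAP	418	10q32.1	False
MPZ5p	184	13q24-q25	False
MPZ3p	291	13q24-q25	False
ACT	254	12q11	True
ALB	206	14p22	False
AFP	252	14p21	False
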