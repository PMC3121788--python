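amplicon	age	zone	symbol
NFM	P0	D	+
NFM	P0	P	+
NFM	P0	VC	+
NFM	P0	E	-
NFL	P0	D	+
NFL	P0	P	+
NFL	P0	VC	+
NFL	P0	E	±
MBP	P0	D	+
MBP	P0	P	+
MBP	P0	VC	+
MBP	P0	E	+
GFAP	P0	D	+
GFAP	P0	P	±
GFAP	P0	VC	-
GFAP	P0	E	-
MPZ5p	P0	D	+
MPZ5p	P0	P	+
MPZ5p	P0	VC	+
MPZ5p	P0	E	+
MPZ3p	P0	D	+
MPZ3p	P0	P	±
MPZ3p	P0	VC	-
MPZ3p	P0	E	-
ACT	P0	D	+
ACT	P0	P	+
ACT	P0	VC	+
ACT	P0	E	±
ALB	P0	D	+
ALB	P0	P	+
ALB	P0	VC	+
ALB	P0	E	±
AFP	P0	D	+
AFP	P0	P	+
AFP	P0	VC	+
AFP	P0	E	±
NFM	P7	D	+
NFM	P7	P	+
NFM	P7	VC	±
NFM	P7	E	-
NFL	P7	D	+
NFL	P7	P	+
NFL	P7	VC	±
NFL	P7	E	-
MBP	P7	D	+
MBP	P7	P	+
MBP	P7	VC	+
MBP	P7	E	+
GFAP	P7	D	+
GFAP	P7	P	-
GFAP	P7	VC	-
GFAP	P7	E	-
MPZ5p	P7	D	+
MPZ5p	P7	P	+
MPZ5p	P7	VC	+
MPZ5p	P7	E	+
MPZ3p	P7	D	+
MPZ3p	P7	P	-
MPZ3p	P7	VC	-
MPZ3p	P7	E	-
ACT	P7	D	+
ACT	P7	P	+
ACT	P7	VC	+
ACT	P7	E	-
ALB	P7	D	+
ALB	P7	P	+
ALB	P7	VC	+
ALB	P7	E	-
AFP	P7	D	+
AFP	P7	P	+
AFP	P7	VC	+
AFP	P7	E	-
NFM	P80	D	+
NFM	P80	P	+
NFM	P80	VC	±
NFM	P80	E	-
NFL	P80	D	+
NFL	P80	P	+
NFL	P80	VC	+
NFL	P80	E	±
MBP	P80	D	+
MBP	P80	P	+
MBP	P80	VC	+
MBP	P80	E	±
GFAP	P80	D	+
GFAP	P80	P	+
GFAP	P80	VC	±
GFAP	P80	E	-
MPZ5p	P80	D	+
MPZ5p	P80	P	+
MPZ5p	P80	VC	+
MPZ5p	P80	E	+
MPZ3p	P80	D	+
MPZ3p	P80	P	+
MPZ3p	P80	VC	±
MPZ3p	P80	E	-
ACT	P80	D	+
ACT	P80	P	+
ACT	P80	VC	+
ACT	P80	E	-
ALB	P80	D	+
ALB	P80	P	+
ALB	P80	VC	+
ALB	P80	E	-
AFP	P80	D	+
AFP	P80	P	+
AFP	P80	VC	+
AFP	P80	E	-
NFM	P540	D	+
NFM	P540	P	±
NFM	P540	VC	-
NFM	P540	E	-
NFL	P540	D	+
NFL	P540	P	±
NFL	P540	VC	-
NFL	P540	E	-
MBP	P540	D	+
MBP	P540	P	+
MBP	P540	VC	±
MBP	P540	E	-
GFAP	P540	D	+
GFAP	P540	P	-
GFAP	P540	VC	-
GFAP	P540	E	-
MPZ5p	P540	D	+
MPZ5p	P540	P	±
MPZ5p	P540	VC	-
MPZ5p	P540	E	-
MPZ3p	P540	D	+
MPZ3p	P540	P	-
MPZ3p	P540	VC	-
MPZ3p	P540	E	-
ACT	P540	D	+
ACT	P540	P	±
ACT	P540	VC	-
ACT	P540	E	-
ALB	P540	D	+
ALB	P540	P	±
ALB	P540	VC	-
ALB	P540	E	-
AFP	P540	D	+
AFP	P540	P	±
AFP	P540	VC	-
AFP	P540	E	-
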