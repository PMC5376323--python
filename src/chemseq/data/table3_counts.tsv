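id	length	D	E	R	H	K	Y	F	W	I	L	V	A	G	P	M	C	S	T	Q	N
PpcA	91	4	6	0	6	19	0	4	0	3	4	5	10	11	4	3	7	2	1	1	1
PpcB	91	3	5	0	6	15	0	4	0	3	5	3	11	10	3	4	6	2	8	1	2
PpcC	95	5	4	5	7	9	1	3	0	8	4	4	9	15	5	3	6	1	5	1	0
PpcD	92	3	6	1	7	15	0	2	1	2	5	6	13	12	1	3	7	0	6	0	2
PpcE	90	2	4	6	6	10	1	5	0	4	5	6	8	8	3	2	6	4	8	0	2
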