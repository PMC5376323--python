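pattern	id	position	residues
624621	PpcA	71	CKGCHE
624621	PpcB	71	CKGCHE
624621	PpcC	71	CKGCHE
624621	PpcD	48	CTGCHK
624621	PpcE	70	CKGCHE
44441	PpcA	18	AFAAD
44441	PpcB	18	ALAAD
44441	PpcC	18	AGAID
44441	PpcD	24	AVAHD
44441	PpcE	18	GLAAD
2222	PpcA	37	HKAH
2222	PpcB	37	HKKH
2222	PpcC	37	HKKH
2222	PpcD	38	HKKH
2222	PpcE	37	HKRH
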