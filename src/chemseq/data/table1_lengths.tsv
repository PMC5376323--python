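id	length	chain_start	chain_end	accession
PpcA	91	21	91	Q8GGK7
PpcB	91	21	91	Q74G83
PpcC	95	21	95	Q74G82
PpcD	92	21	92	Q74ED8
PpcE	90	21	90	Q74CB4
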