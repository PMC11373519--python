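# child	parent	side
A	D	-
B	E	-
C	F	-
D	E	L
D	F	R
E	G	-
F	G	-
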