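# child	parent	intervals
## sequence_length=10
A	E	0,2
A	F	2,10
B	G	0,10
C	E	7,10
C	F	0,7
D	H	0,10
E	I	0,10
F	J	0,10
G	J	0,10
H	L	0,10
I	N	0,10
J	N	0,10
K	N	0,10
L	N	0,10
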