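# child	parent	intervals
## sequence_length=7
A	D	0,7
B	E	0,7
C	I	0,7
D	F	0,2
D	H	2,7
E	F	0,2
E	H	2,7
F	G	0,2
G	K	0,2
H	J	2,7
I	K	0,2
I	M	2,7
J	L	2,7
L	N	2,4
L	O	4,7
M	N	4,7
M	O	2,4
N	P	2,7
O	P	2,7
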