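# child	parent	side
A	D	-
B	E	-
C	I	-
D	F	L
D	H	R
E	F	L
E	H	R
F	G	-
G	J	R
G	K	L
H	J	-
I	K	L
I	M	R
J	L	-
K	Q	-
L	N	L
L	O	R
M	N	R
M	O	L
N	P	-
O	P	-
P	Q	-
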