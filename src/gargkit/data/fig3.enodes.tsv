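# id	kind	breakpoint	time
## sequence_length=7
A	sample		0
B	sample		0
C	sample		0
D	recombination	2	1
E	recombination	2	2
F	common_ancestor		3
G	recombination	5	4
H	common_ancestor		5
I	recombination	2	6
J	common_ancestor		7
K	common_ancestor		8
L	recombination	4	9
M	recombination	4	10
N	common_ancestor		11
O	common_ancestor		12
P	common_ancestor		13
Q	common_ancestor		14
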