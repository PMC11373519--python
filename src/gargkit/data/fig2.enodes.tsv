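# id	kind	breakpoint	time
## sequence_length=10
A	sample		0
B	sample		0
C	sample		0
D	recombination	5	1
E	common_ancestor		2
F	common_ancestor		3
G	common_ancestor		4
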