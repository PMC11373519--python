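# id	time	is_sample	metadata
A	0	1	kind=sample
B	0	1	kind=sample
C	0	1	kind=sample
D	1	0	kind=recombination breakpoint=2.0
E	2	0	kind=recombination breakpoint=2.0
F	3	0	kind=common_ancestor
G	4	0	kind=recombination breakpoint=5.0
H	5	0	kind=common_ancestor
I	6	0	kind=recombination breakpoint=2.0
J	7	0	kind=common_ancestor
K	8	0	kind=common_ancestor
L	9	0	kind=recombination breakpoint=4.0
M	10	0	kind=recombination breakpoint=4.0
N	11	0	kind=common_ancestor
O	12	0	kind=common_ancestor
P	13	0	kind=common_ancestor
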