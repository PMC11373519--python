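# id	time	is_sample	metadata
A	0	1	individual=d1
B	0	1	individual=d1
C	0	1	individual=d2
D	0	1	individual=d2
E	1	0	individual=d3
F	1	0	individual=d3
G	1	0	individual=d4
H	1	0	individual=d4
I	2	0	individual=d5
J	2	0	individual=d5
K	2	0	individual=d6
L	2	0	individual=d6
M	3	0	individual=d7
N	3	0	individual=d7
O	3	0	individual=d8
P	3	0	individual=d8
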