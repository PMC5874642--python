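# N-end-rule half-life estimates by N-terminal residue (v1)
# residue	mammalian_reticulocyte_invitro	yeast_invivo	ecoli_invivo
A	4.4 hour	>20 hour	>10 hour
C	1.2 hour	>20 hour	>10 hour
D	1.1 hour	3 min	>10 hour
E	1 hour	30 min	>10 hour
F	1.1 hour	3 min	2 min
G	30 hour	>20 hour	>10 hour
H	3.5 hour	10 min	>10 hour
I	20 hour	30 min	>10 hour
K	1.3 hour	3 min	2 min
L	5.5 hour	3 min	2 min
M	30 hour	>20 hour	>10 hour
N	1.4 hour	3 min	>10 hour
P	>20 hour	>20 hour	?
Q	0.8 hour	10 min	>10 hour
R	1 hour	2 min	2 min
S	1.9 hour	>20 hour	>10 hour
T	7.2 hour	>20 hour	>10 hour
V	100 hour	>20 hour	>10 hour
W	2.8 hour	3 min	2 min
Y	2.8 hour	10 min	2 min
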