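# Bjellqvist pKa set used by the ExPASy pI model (v1)
# kind	key	pka
positive	Nterm	7.5
positive	K	10.0
positive	R	12.0
positive	H	5.98
negative	Cterm	3.55
negative	D	4.05
negative	E	4.45
negative	C	9.0
negative	Y	10.0
nterm_residue	A	7.59
nterm_residue	M	7.0
nterm_residue	S	6.93
nterm_residue	P	8.36
nterm_residue	T	6.82
nterm_residue	V	7.44
nterm_residue	E	7.7
cterm_residue	D	4.55
cterm_residue	E	4.75
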