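# Guruprasad dipeptide instability weight values DIWV (v1)
# first	second	weight
A	A	1.0
A	C	44.94
A	D	-7.49
A	E	1.0
A	F	1.0
A	G	1.0
A	H	-7.49
A	I	1.0
A	K	1.0
A	L	1.0
A	M	1.0
A	N	1.0
A	P	20.26
A	Q	1.0
A	R	1.0
A	S	1.0
A	T	1.0
A	V	1.0
A	W	1.0
A	Y	1.0
C	A	1.0
C	C	1.0
C	D	20.26
C	E	1.0
C	F	1.0
C	G	1.0
C	H	33.6
C	I	1.0
C	K	1.0
C	L	20.26
C	M	33.6
C	N	1.0
C	P	20.26
C	Q	-6.54
C	R	1.0
C	S	1.0
C	T	33.6
C	V	-6.54
C	W	24.68
C	Y	1.0
D	A	1.0
D	C	1.0
D	D	1.0
D	E	1.0
D	F	-6.54
D	G	1.0
D	H	1.0
D	I	1.0
D	K	-7.49
D	L	1.0
D	M	1.0
D	N	1.0
D	P	1.0
D	Q	1.0
D	R	-6.54
D	S	20.26
D	T	-14.03
D	V	1.0
D	W	1.0
D	Y	1.0
E	A	1.0
E	C	44.94
E	D	20.26
E	E	33.6
E	F	1.0
E	G	1.0
E	H	-6.54
E	I	20.26
E	K	1.0
E	L	1.0
E	M	1.0
E	N	1.0
E	P	20.26
E	Q	20.26
E	R	1.0
E	S	20.26
E	T	1.0
E	V	1.0
E	W	-14.03
E	Y	1.0
F	A	1.0
F	C	1.0
F	D	13.34
F	E	1.0
F	F	1.0
F	G	1.0
F	H	1.0
F	I	1.0
F	K	-14.03
F	L	1.0
F	M	1.0
F	N	1.0
F	P	20.26
F	Q	1.0
F	R	1.0
F	S	1.0
F	T	1.0
F	V	1.0
F	W	1.0
F	Y	33.601
G	A	-7.49
G	C	1.0
G	D	1.0
G	E	-6.54
G	F	1.0
G	G	13.34
G	H	1.0
G	I	-7.49
G	K	-7.49
G	L	1.0
G	M	1.0
G	N	-7.49
G	P	1.0
G	Q	1.0
G	R	1.0
G	S	1.0
G	T	-7.49
G	V	1.0
G	W	13.34
G	Y	-7.49
H	A	1.0
H	C	1.0
H	D	1.0
H	E	1.0
H	F	-9.37
H	G	-9.37
H	H	1.0
H	I	44.94
H	K	24.68
H	L	1.0
H	M	1.0
H	N	24.68
H	P	-1.88
H	Q	1.0
H	R	1.0
H	S	1.0
H	T	-6.54
H	V	1.0
H	W	-1.88
H	Y	44.94
I	A	1.0
I	C	1.0
I	D	1.0
I	E	44.94
I	F	1.0
I	G	1.0
I	H	13.34
I	I	1.0
I	K	-7.49
I	L	20.26
I	M	1.0
I	N	1.0
I	P	-1.88
I	Q	1.0
I	R	1.0
I	S	1.0
I	T	1.0
I	V	-7.49
I	W	1.0
I	Y	1.0
K	A	1.0
K	C	1.0
K	D	1.0
K	E	1.0
K	F	1.0
K	G	-7.49
K	H	1.0
K	I	-7.49
K	K	1.0
K	L	-7.49
K	M	33.6
K	N	1.0
K	P	-6.54
K	Q	24.64
K	R	33.6
K	S	1.0
K	T	1.0
K	V	-7.49
K	W	1.0
K	Y	1.0
L	A	1.0
L	C	1.0
L	D	1.0
L	E	1.0
L	F	1.0
L	G	1.0
L	H	1.0
L	I	1.0
L	K	-7.49
L	L	1.0
L	M	1.0
L	N	1.0
L	P	20.26
L	Q	33.6
L	R	20.26
L	S	1.0
L	T	1.0
L	V	1.0
L	W	24.68
L	Y	1.0
M	A	13.34
M	C	1.0
M	D	1.0
M	E	1.0
M	F	1.0
M	G	1.0
M	H	58.28
M	I	1.0
M	K	1.0
M	L	1.0
M	M	-1.88
M	N	1.0
M	P	44.94
M	Q	-6.54
M	R	-6.54
M	S	44.94
M	T	-1.88
M	V	1.0
M	W	1.0
M	Y	24.68
N	A	1.0
N	C	-1.88
N	D	1.0
N	E	1.0
N	F	-14.03
N	G	-14.03
N	H	1.0
N	I	44.94
N	K	24.68
N	L	1.0
N	M	1.0
N	N	1.0
N	P	-1.88
N	Q	-6.54
N	R	1.0
N	S	1.0
N	T	-7.49
N	V	1.0
N	W	-9.37
N	Y	1.0
P	A	20.26
P	C	-6.54
P	D	-6.54
P	E	18.38
P	F	20.26
P	G	1.0
P	H	1.0
P	I	1.0
P	K	1.0
P	L	1.0
P	M	-6.54
P	N	1.0
P	P	20.26
P	Q	20.26
P	R	-6.54
P	S	20.26
P	T	1.0
P	V	20.26
P	W	-1.88
P	Y	1.0
Q	A	1.0
Q	C	-6.54
Q	D	20.26
Q	E	20.26
Q	F	-6.54
Q	G	1.0
Q	H	1.0
Q	I	1.0
Q	K	1.0
Q	L	1.0
Q	M	1.0
Q	N	1.0
Q	P	20.26
Q	Q	20.26
Q	R	1.0
Q	S	44.94
Q	T	1.0
Q	V	-6.54
Q	W	1.0
Q	Y	-6.54
R	A	1.0
R	C	1.0
R	D	1.0
R	E	1.0
R	F	1.0
R	G	-7.49
R	H	20.26
R	I	1.0
R	K	1.0
R	L	1.0
R	M	1.0
R	N	13.34
R	P	20.26
R	Q	20.26
R	R	58.28
R	S	44.94
R	T	1.0
R	V	1.0
R	W	58.28
R	Y	-6.54
S	A	1.0
S	C	33.6
S	D	1.0
S	E	20.26
S	F	1.0
S	G	1.0
S	H	1.0
S	I	1.0
S	K	1.0
S	L	1.0
S	M	1.0
S	N	1.0
S	P	44.94
S	Q	20.26
S	R	20.26
S	S	20.26
S	T	1.0
S	V	1.0
S	W	1.0
S	Y	1.0
T	A	1.0
T	C	1.0
T	D	1.0
T	E	20.26
T	F	13.34
T	G	-7.49
T	H	1.0
T	I	1.0
T	K	1.0
T	L	1.0
T	M	1.0
T	N	-14.03
T	P	1.0
T	Q	-6.54
T	R	1.0
T	S	1.0
T	T	1.0
T	V	1.0
T	W	-14.03
T	Y	1.0
V	A	1.0
V	C	1.0
V	D	-14.03
V	E	1.0
V	F	1.0
V	G	-7.49
V	H	1.0
V	I	1.0
V	K	-1.88
V	L	1.0
V	M	1.0
V	N	1.0
V	P	20.26
V	Q	1.0
V	R	1.0
V	S	1.0
V	T	-7.49
V	V	1.0
V	W	1.0
V	Y	-6.54
W	A	-14.03
W	C	1.0
W	D	1.0
W	E	1.0
W	F	1.0
W	G	-9.37
W	H	24.68
W	I	1.0
W	K	1.0
W	L	13.34
W	M	24.68
W	N	13.34
W	P	1.0
W	Q	1.0
W	R	1.0
W	S	1.0
W	T	-14.03
W	V	-7.49
W	W	1.0
W	Y	1.0
Y	A	24.68
Y	C	1.0
Y	D	24.68
Y	E	-6.54
Y	F	1.0
Y	G	-7.49
Y	H	13.34
Y	I	1.0
Y	K	1.0
Y	L	1.0
Y	M	44.94
Y	N	1.0
Y	P	13.34
Y	Q	1.0
Y	R	-15.91
Y	S	1.0
Y	T	-7.49
Y	V	1.0
Y	W	-9.37
Y	Y	13.34
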