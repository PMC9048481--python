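# invertebrate comparison panel with its own betaIII reference column
# as printed (note 189 = L here vs I in table1); motif rows from the
# printed cluster hexamers and region tetramers
position	betaIII	So1	So2	Ed	Ob	Do	Ac	Cg	Ls1	Ls2	Hd	Dm1	Dm2	Em	Nc	At	Gi	Tp
33	S	T	T	S	S	T	T	T	T	T	T	T	G	M	S	T	S	T
35	N	S	T	V	V	T	T	T	T	N	T	A	S	S	V	Q	E	T
37	V	H	H	Q	Q	H	H	H	H	H	H	R	L	N	N	V	R	H
48	S	N	S	Y	Y	N	T	N	N	N	N	N	E	N	N	D	N	N
55	S	T	T	S	S	T	T	T	S	S	T	S	S	Q	S	S	A	T
56	S	G	G	S	S	G	G	G	G	G	G	G	G	G	G	G	G	G
57	H	G	G	G	G	G	G	G	G	G	G	G	G	G	N	G	G	G
80	A	P	P	P	P	P	P	P	P	A	P	P	P	P	P	P	P	P
83	H	Q	Q	Q	N	Q	Q	Q	Q	Q	Q	Q	Q	K	Q	Q	Q	Q
84	L	L	I	L	L	I	I	I	I	L	I	L	L	L	L	I	I	L
91	I	V	V	V	V	V	V	V	V	V	V	V	V	I	V	V	V	V
124	C	A	C	C	C	A	S	A	A	S	A	A	C	C	A	A	S	A
125	E	E	E	E	E	E	E	E	E	E	E	E	E	E	E	E	E	E
126	N	S	N	G	G	S	N	S	N	N	S	S	N	A	G	N	A	G
127	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	S	C	C
128	D	D	D	E	E	D	D	D	D	D	D	D	D	D	D	D	D	D
129	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C
155	V	I	I	I	I	I	M	I	M	M	I	I	I	I	I	I	I	V
189	L	I	V	V	V	V	V	V	V	V	V	V	I	V	V	V	V	V
218	A	T	T	T	P	T	T	T	T	S	T	T	S	P	S	A	T	T
237	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T
238	T	T	T	T	T	T	T	T	T	T	T	T	T	T	V	C	S	C
239	S	C	C	C	C	C	C	C	C	S	C	C	C	S	S	C	C	C
240	L	L	L	L	L	L	L	L	L	L	L	L	L	L	L	L	L	L
275	A	S	S	S	S	S	S	S	S	S	S	S	S	S	S	S	S	S
315	T	T	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A
332	A	N	N	S	S	N	N	N	N	N	N	N	A	E	N	N	N	N
333	I	I	V	I	I	V	V	V	V	V	V	I	V	T	V	I	I	V
335	S	S	N	N	N	N	N	N	N	N	N	N	N	T	N	N	N	N
351	V	T	T	T	T	T	T	T	Q	T	T	T	T	T	T	V	V	S
364	S	S	S	S	S	S	S	S	S	S	S	S	S	A	S	A	A	A
365	S	A	A	A	A	A	A	A	A	A	S	A	S	G	S	S	A	V
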