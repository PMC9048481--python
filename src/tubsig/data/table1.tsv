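# vertebrate isotype residue matrix at the 25 signature positions,
# plus motif rows 125-129 / 237-240 assembled from the printed cluster
# hexamers and region tetramers; the vertebrate betaIII columns carry
# CENCDC/TTSL (237/238/240 for Xl and Ss extrapolated from the HMBG rows)
position	betaIII_Hs	betaIII_Mm	betaIII_Gg	betaIII_Gj	betaIII_Xl	betaIII_Ss	betaI	betaIIA	betaIIB	betaIVA	betaIVB	betaV	betaVI
33	S	S	S	S	C	T	T	T	T	L	T	A	A
35	N	N	N	N	N	N	T	S	T	T	T	G	S
37	V	V	V	V	I	E	H	H	H	H	H	V	R
48	S	S	S	S	S	S	S	V	N	N	N	N	S
55	S	S	S	S	S	S	T	A	T	T	T	S	Y
56	S	S	S	S	S	S	G	G	G	G	G	S	G
57	H	H	H	H	L	S	G	N	N	G	G	Q	R
80	A	A	A	A	A	T	P	P	P	P	P	P	K
83	H	H	H	H	H	Q	Q	Q	Q	Q	Q	Q	A
84	L	L	L	L	L	L	I	I	I	I	I	I	L
91	I	I	I	I	I	I	V	V	V	V	V	I	V
124	C	C	C	C	C	C	A	S	S	A	A	C	S
125	E	E	E	E	E	E	E	E	E	E	E	E	E
126	N	N	N	N	N	N	S	S	S	S	S	H	S
127	C	C	C	C	C	C	C	C	C	C	C	C	C
128	D	D	D	D	D	D	D	D	D	D	D	D	D
129	C	C	C	C	C	C	C	C	C	C	C	C	C
155	V	V	V	V	V	I	I	I	I	I	I	I	I
189	I	I	I	I	I	I	V	V	V	V	V	V	I
218	A	A	A	A	A	P	T	T	T	T	T	T	T
237	T	T	T	T	T	T	T	T	T	T	T	T	T
238	T	T	T	T	T	T	T	T	T	T	T	T	T
239	S	S	S	S	S	S	C	C	C	C	C	S	S
240	L	L	L	L	L	L	L	L	L	L	L	L	L
275	A	A	A	A	A	A	S	S	S	S	S	S	A
315	T	T	T	A	T	M	A	A	A	A	A	T	C
332	A	A	A	A	A	A	N	N	N	S	V	A	S
333	I	I	I	I	I	I	V	V	V	V	Q	I	V
335	S	S	S	S	S	S	N	N	N	S	K	S	T
351	V	V	V	V	V	V	T	T	T	T	T	V	V
364	S	S	S	S	S	S	A	S	S	A	P	A	A
365	S	S	S	S	S	A	V	A	A	A	A	S	A
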