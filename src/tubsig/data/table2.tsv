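# betaVI comparison panel; motif rows are filled only where printed or
# stated (human/chicken/cod betaVI, betaIII, betaV), '-' elsewhere
position	betaVI_Hs	betaVI_Mm	betaVI_Gg	betaVI_Duck	betaVI_Gecko	betaVI_Turtle	betaVI_Xl	betaVI_Channa	betaVI_Molly	betaVI_Cod	betaIII_Hs	betaV_Hs
33	A	A	A	A	G	T	Q	T	T	T	S	A
35	S	S	N	N	N	N	S	F	L	N	N	G
37	R	C	C	R	C	H	H	E	E	V	V	V
48	S	S	N	N	N	N	N	N	N	N	S	N
55	Y	Y	Y	Y	Y	H	H	H	H	S	S	S
56	G	G	S	S	S	S	S	G	G	S	S	S
57	R	K	H	H	H	K	H	G	G	N	H	Q
80	K	R	K	K	K	K	S	R	R	T	A	P
83	A	V	P	P	P	P	P	A	A	Q	H	Q
84	L	L	L	L	L	L	L	L	L	L	L	I
91	V	V	I	I	I	I	I	I	I	I	I	I
124	S	S	C	C	C	C	S	S	S	C	C	C
125	E	-	E	-	-	-	-	-	-	E	E	E
126	S	S	S	S	C	S	S	S	S	N	N	H
127	C	-	C	-	-	-	-	-	-	C	C	C
128	D	-	D	-	-	-	-	-	-	D	D	D
129	C	-	C	-	-	-	-	-	-	C	C	C
155	I	I	I	I	I	I	I	I	I	I	V	I
189	I	I	I	I	I	I	I	V	V	V	I	V
218	T	T	T	T	P	R	T	T	T	T	A	T
237	T	-	T	-	-	-	-	-	-	-	T	T
238	T	-	T	-	-	-	-	-	-	-	T	T
239	S	S	S	S	S	S	S	S	S	S	S	S
240	L	-	L	-	-	-	-	-	-	-	L	L
275	A	A	A	A	A	A	S	A	P	A	A	S
315	C	C	C	C	C	C	G	G	G	T	T	T
332	S	S	S	A	S	A	S	A	A	N	A	A
333	V	I	V	V	I	I	V	I	M	V	I	I
335	T	T	T	T	T	T	S	Q	Q	N	S	S
351	V	V	V	V	V	V	V	V	V	V	V	V
364	A	A	A	A	S	A	A	A	A	S	S	A
365	A	A	A	A	A	A	S	S	S	A	S	S
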