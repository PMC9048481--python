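sample_id	isotype	position	reference	observed	grade	chemo
patient1	betaIVB	124	A	C	high	t
patient1	betaIVB	126	S	N	high	t
patient1	betaIVB	155	I	V	high	n,t
patient1	betaIVB	189	V	I	high	t
patient1	betaIVB	218	T	A	high	t
patient1	betaIVB	239	C	S	high	t
patient2	betaIVB	275	S	A	high	n
patient2	betaIVB	315	A	T	high	n
patient2	betaIVB	332	V	A	high	n,d
patient2	betaIVB	333	Q	I	high	n,d
patient2	betaIVB	335	K	S	high	n,d
patient2	betaIVB	351	T	V	high	n,d
patient2	betaIVB	365	A	S	high	n,d
patient3	betaIVB	332	V	A	high	n,d
patient3	betaIVB	333	Q	I	high	n,d
patient3	betaIVB	335	K	S	high	n,d
patient3	betaIVB	351	T	V	high	n,d
patient3	betaIVB	365	A	S	high	n,d
lowgrade1	betaI	239	C	L	low	unknown
lowgrade2	betaI	239	C	Y	low	unknown
lowgrade3	betaI	239	C	R	low	unknown
lowgrade4	betaI	239	C	P	low	unknown
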