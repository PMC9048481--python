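position	structure_location	chemo
33	H1/S2 Loop	t
35	H1/S2 Loop	t
37	H1/S2 Loop	-
48	H1/S2 Loop	n
55	H1/S2 Loop	-
56	H1/S2 Loop	-
57	H1/S2 Loop	-
80	H2/S3 Loop	-
83	H2/S3 Loop	-
84	H2/S3 Loop	-
91	β-Sheet S3	-
124	α-Helix H3	t
126	H3/S4 Loop	t
155	α-Helix H4	n,t
189	α-Helix H5	t
218	H6/H7 Loop	t
239	H7/H8 Loop	t
275	S7/H9 Loop	n
315	β-Sheet S8	n
332	α-Helix H10	n,d
333	α-Helix H10	n,d
335	α-Helix H10	n,d
351	β-Sheet S9	n,d
364	β-Sheet S10	-
365	β-Sheet S10	n,d
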