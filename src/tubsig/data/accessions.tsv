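label	species	accession
betaIII_Hs	Homo sapiens	AAL28094
betaIII_Mm	Mus musculus	NP_075768
betaIII_Bos	Bos taurus	NP_001070595
betaIII_Gg	Gallus gallus	NP_001383082
betaIII_Gj	Gekko japonicus	AFD53918
betaIII_Xl	Xenopus laevis	NP_001088455
betaIII_Ss	Salmo salar	XP_013982514
betaI	Homo sapiens	BAE78618
betaIIA	Homo sapiens	NP_001060
betaIIB	Homo sapiens	NP_821080
betaIVA	Homo sapiens	NP_001276058
betaIVB	Homo sapiens	AAN87335
betaV	Homo sapiens	Q9BUF5
betaVI_Hs	Homo sapiens	NP_110400
betaVI_Mm	Mus musculus	NP_001074440
betaVI_Gg	Gallus gallus	NP_990776
betaVI_Duck	Anas platyrhynchos	XP_005010451
betaVI_Gecko	Gekko japonicus	XP_015268461
betaVI_Turtle	Chelonia mydas	XP_007059846
betaVI_Xl	Xenopus laevis	XP_031750537
betaVI_Channa	Channa argus	KAF3690084
betaVI_Molly	Poecilia formosa	XP_007548412
betaVI_Cod	Gadus morhua	XP_030204426
So1	Sepia officinalis isotype 1	CCG28034
So2	Sepia officinalis isotype 2	CCG28035
Ed	Enteroctopus dofleini	AAA16611
Ob	Octopus bimaculoides	KOF91916
Do	Doryteuthis pealeii	AAU11524
Ac	Aplysia californica	NP_001191530
Cg	Crassostrea gigas	BAD80737
Ls1	Lymnaea stagnalis isotype 1	AOV18890
Ls2	Lymnaea stagnalis isotype 2	AOV18892
Hd	Haliotis diversicolor	AEW42984
Dm1	Drosophila melanogaster 56D isoform B	NP_523795
Dm2	Drosophila melanogaster 60D isoform B	NP_001286835
Em	Echinococcus multilocularis	CDI98193
Nc	Neurospora crassa	AAA33617
At	Arabidopsis thaliana	AAA32757
Gi	Giardia lamblia	XP_001707388
Tp	Tetrahymena pyriformis	CAA31258
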