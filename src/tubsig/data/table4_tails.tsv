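group	label	tail
vertebrate_betaIII	Homo	YQDATAEEEGEMYEDDEEESEAQGPK
vertebrate_betaIII	Mus	YQDATAEEEGEMYEDDDEESEAQGPK
vertebrate_betaIII	Gallus	YQDATAEEEGEMYEDDEEESEAQGAK
vertebrate_betaIII	Gekko	YQDATAEEEGEMYEDDEEESEAQGAK
vertebrate_betaIII	Xenopus	YQDATAEEEGEMYEDDEEESEAQGK
vertebrate_betaIII	Salmo	YQDATTEEEGEMYEDDEEESESQAR
human_isotype	βI	YQDATAEEEEDFGEEAEEEA
human_isotype	βIIA	YQDATADEQGEFEEEEGEDEA
human_isotype	βIIB	YQDATADEQGEFEEEEGEDEA
human_isotype	βIVA	YQDATAEEGEFEEEAEEEVA
human_isotype	βIVB	YQDATAEEEGEFEEGAEEEVA
human_isotype	βV	YQDATANDGEEAFEDEEEEIDG
human_isotype	βVI	FQDAKAVLEEDEEVTEEAEMEPEDKGH
cephalopod	Sepia officinalis* Isotype 1	YQDATAEEEAEMDEEEEDVA
cephalopod	Sepia officinalis* Isotype 2	YQDATTEEEILIEEAEDEEA
cephalopod	Enteroctopus dofleini	YQEARSTDSDEYDNEEYYNQQEE
cephalopod	Octopus bimaculoides	YQEARATDSDEYDDEDQYNEQE
cephalopod	Doryteuthis pealii	YQDATAEEEGEFEEEGEEDA
other_mollusk	Aplysia californica	YQDATAEDEGEFDEEEGDEGGEEYA
other_mollusk	Crassostrea gigas	YQDATAEEEGEFEEEEGEEEAQ
other_mollusk	Lymnaea stagnalis* Isotype 1	YQDATAEDEGEFDEEEAEGEGQEYA
other_mollusk	Lymnaea stagnalis* Isotype 2	YQEATIDEDVEVEEGADEDAGDL
other_mollusk	Haliotis diversicolor	YQDATAEEEGEFDEEEGEADEA
other_invertebrate	D. melanogaster* (56D, Isoform B)	YQEATADEDAEFEEEQEAEVDEN
other_invertebrate	D. melanogaster* (60D, Isoform B)	LVSEYQQYQEATADDEFDPEVNQEEVEGDCI
other_invertebrate	Nasonia vitripennis	YQEATTEEDFETEDAGDDFETCDQE
other_invertebrate	Bombyx mori	YQEATAEDDTEFDQEDLEELAQDEHHD
other_invertebrate	Echinococcus multilocularis	EYQQYQEVGIDDDYGEEEAAPEE
other_eukaryote	Neurospora crassa	YQDAGVDEEEEEYEEEAPLEGEE
other_eukaryote	Arabidopsis thaliana	YQDATAGEEEYEEEEEEYET
other_eukaryote	Giardia lamblia	YQEAGVDEGEEFEEEEDFGDEYA
other_eukaryote	Tetrahymena pyriformis	YQDATAEEEGEFEEEEGEN
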