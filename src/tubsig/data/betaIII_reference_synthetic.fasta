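>BIII_SYNTH synthetic beta-III-like reference, 450 aa; landmark residues planted from the curated signature scheme, filler is fixed pseudo-random
TEEAYYTMVLCLVRNYKQPRTVAWSGMTTKLVSENTVMTFGTMRLDRSLRDTDQSSHTYI
DDAAAALQPRGALALYSEDATSHLVPGRRLIVLGGRFGRCEPLPVEIGHHDWNSVLINNL
LIKCENCDCKQIKFATIEQNTKFAAYVASQLKGAVWPKPDPNEGALTIKDNVKHLPKVSR
TFRKIGGAIKGTPRCIGTQKYAQVSKYDSAFFKAVISAENDVSNDYLTCQVGFSLGTTSL
GSKNKKAKSVRYTLGLVRNKNLETDELKTMALQGASQASDCFQLSAIAPGRYIQATMKEH
PGADVITSKPQVGATVDEKTCEECQIVLGTIAIFSIIQNKNWTYMAVVQDVIYCLHRTGS
STTSSVRTCPQCKEEKMCRIDLGSRFELFTTVTHYYDEDIVENWIKEKLPEGPIPDGCPV
VLHMYQDATAEEEGEMYEDDEEESEAQGPK
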