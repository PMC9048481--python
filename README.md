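# tubsig

Sequence analysis of β-tubulin isotypes, centered on the residue signature of
βIII — the isotype found almost exclusively in neurons and aggressive cancers.

Vertebrate β-tubulin isotypes (βI, βIIA/B, βIII, βIVA/B, βV, βVI) are >90%
identical, yet they differ at a small set of strongly conserved positions.
For βIII there are 25 such canonical positions, and three curated subsets of
them carry most of the biology:

- **universal-8** `{35, 56, 84, 124, 189, 239, 275, 351}` — conserved in every
  vertebrate βIII examined and distinct from βI/βII/βIV;
- **βV-12** `{37, 55, 56, 91, 124, 239, 315, 332, 333, 335, 351, 365}` — where
  human βV carries the βIII residue;
- **cancer-mutated-17** — signature positions at which βI/βIIA/βIVB clones in
  breast tumors mutated *toward* the βIII residue.

Two positional motifs sit inside the signature: the CXXCXC cysteine cluster at
canonical 124–129 (CENCDC in human βIII) and serine rather than the easily
oxidized cysteine at position 239, reported as the 237–240 tetramer (TTSL vs
TTCL). The package is for anyone asking whether a β-tubulin — a cephalopod
isotype, an invertebrate paralog, a tumor variant — "looks like βIII": it maps
sequences onto the canonical human βIII coordinate system by pairwise global
alignment, extracts the signature profile, counts matches per subset, calls
the motifs, profiles C-terminal tails, and classifies substitution events as
toward-βIII (convergent) or not.

All canonical positions are 1-based on human βIII. The bundled reference
(`data/betaIII_reference_synthetic.fasta`) is a *synthetic* 450-residue
βIII-like sequence — all landmark residues are planted from the curated
tables, the rest is fixed filler — and defines the coordinate system; the
curated residue matrices for the vertebrate isotypes, the βVI panel, and the
invertebrate panel ship as versioned TSV fixtures (`table1`–`table3`, plus
`table4` for C-terminal tails).

## Worked example

Score the invertebrate panel against the βIII reference column of the same
table:

```
$ tubsig compare --fixture table3 | head -6
sequence_id  matches_all25  matches_betaIII_and_betaV  matches_vert_betaIII  cluster  cluster_hexamer  region_239
betaIII      25             12                         8                     Yes      CENCDC           TTSL
So1          5              3                          1                     No       AESCDC           TTCL
So2          4              1                          1                     Yes      CENCDC           TTCL
Ed           7              4                          3                     Yes      CEGCEC           TTCL
Ob           7              4                          3                     Yes      CEGCEC           TTCL
```

Reading the *Octopus bimaculoides* (`Ob`) row: of the 25 βIII signature
positions it carries the βIII residue at 7, four of those are also βV
positions and three are in the universal-8 set; it has a complete cysteine
cluster (CEGCEC — cysteines at 124/127/129) but keeps the ancestral C239
(TTCL). The octopi resemble βIII far more than, say, the squid *Doryteuthis*
(`Do`: 1/0/0, no cluster) — the convergence pattern that motivates the
package.

The same works for FASTA input (`--input cohort.fasta`), for C-terminal tails
(`tubsig ctermini --fixture table4`), for mutation-event tables
(`tubsig mutations`, which on the bundled breast-cancer events reports 18
toward-βIII substitutions at 13 distinct positions), and for synthetic cohorts
with ground-truth manifests (`tubsig simulate`).

As a library:

```python
import tubsig

scheme = tubsig.default_scheme()
table3 = tubsig.load_fixture_matrix("table3")
ref = tubsig.table_reference_profile("table3")
tubsig.match_count(table3["Ob"], ref, tubsig.SIGNATURE_POSITIONS)  # -> 7
```

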