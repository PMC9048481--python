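# Methods

## Coordinate system and alignment

Every computation is anchored to 1-based canonical positions on human βIII.
Queries are placed on that system by pairwise global alignment against a
single bundled reference — never by multiple sequence alignment — because
β-tubulins are >90% identical through position ~424 and any reasonable
pairwise scheme recovers the same correspondence; what matters is that the
scheme is deterministic.

The aligner is biopython's `PairwiseAligner` with BLOSUM62, affine gaps
(open −11, extend −1), and free end gaps on the C-terminal side of both
sequences, since tail lengths vary wildly across isotypes and taxa and should
not be penalized. Aligned columns become (sequence index, canonical position)
pairs; query residues opposite reference gaps are recorded as insertions
(after-position, length); reference positions opposite query gaps become
unmapped. The first optimal alignment reported by the aligner is used, which
is deterministic for fixed inputs. If alignment identity (identities over
aligned columns) falls below a floor of 0.40 — a judgment call, configurable —
numbering is refused outright (`NotHomologError`), because canonical
coordinates on a non-homolog are meaningless rather than merely noisy.

The reference is a synthetic 450-residue βIII-like sequence: the 25 signature
residues, the CENCDC cluster (124–129), the TTSL window (237–240), C354, and
the human βIII tail occupying 425–450 are planted from the curated tables;
every other position is fixed pseudo-random filler with a roughly globular
composition. It fixes the coordinate system and exercises the alignment
machinery; it is not the database accession, and conclusions about real
sequences should come from the curated matrices, which are data, not filler.

## The signature scheme

The scheme is the ordered 25 positions (33 … 365) with per-isotype reference
residues loaded from the bundled matrices, plus three curated subsets
(universal-8, βV-12, cancer-mutated-17) and a per-position free-text
structure annotation (helix/sheet/loop placement and chemotherapy notes),
which is carried verbatim and never used in computation.

Two curation choices deserve explanation:

- **The subsets are shipped as constants, not recomputed.** The universal-8
  derivation used many vertebrate species whose residue columns are not part
  of the bundled matrices, so recomputation from the six bundled vertebrate
  βIII columns yields a strictly larger set (13 positions, which properly
  contains the 8 — the tests check exactly this). The
  `conserved_distinct_positions` classifier is provided so users can rerun
  the derivation on any profile sets of their own, under either a strict-all
  or a majority distinctness rule.
- **Each comparison table carries its own βIII reference column, as printed.**
  The vertebrate table gives I at position 189 while the invertebrate table
  prints L there; the published per-taxon match counts are only reproducible
  against the per-table column (e.g. Sepia isotype 1 carries I189 and counts
  5, not 6). Comparisons against a fixture therefore default to that
  fixture's own column.

Match semantics are plain identity of uppercase one-letter codes; `X` and
absent residues never match anything, including themselves. Match counting
over a subset, the identical-position set, and subset overlaps are all
deliberately trivial operations — the value of the package is in the curation
and the coordinate bookkeeping, and the tests pin each operation to an
independent brute-force recount.

## Motifs and C-terminal tails

The cysteine cluster is *positional*: the hexamer is read at canonical
124–129 and called present iff cysteines occupy 124, 127, and 129 (the CXXCXC
topography). No free scan is performed; a cluster elsewhere in a sequence is
not the motif in question. The 237–240 window around position 239 was chosen
to match the printed TTSL/TTCL tetramers; the window's exact bounds are an
implementation inference from those strings.

Tails are split at canonical 425. One printed source note places the excluded
C-terminal region at "431-", but the tail table's entries all begin YQDAT,
and removal of the last 21 residues of the 450-residue protein leaves
position 429 as the new terminus with YQDAT at 425–429; 425 reconciles both
and is the default (`tail_start` is configurable). Tail features are overall
characteristics, not positional identity: length, terminal residue, terminal
basicity (K/R only — histidine is deliberately excluded), acidic residue
count (D+E), and the three βIII landmarks M436/Y437/S444. When a numbering
map is available the landmarks are read at canonical positions, so indels
inside the tail do not break detection; for bare fixture tails they are read
by offset from the assumed tail start.

## Mutation classification

A substitution event (sample, isotype, canonical position, reference residue,
observed residue, grade and chemo annotations) is `toward_betaIII` iff the
position is one of the 25, the observed residue equals the human βIII residue
there, and the event is a real change. Non-signature positions — including
everything C-terminal of the boundary, which the underlying tumor survey did
not sequence — are `off_signature`. Grade and chemotherapy labels are tallied
but never tested for association: the source reports the grade correlation
qualitatively, without per-arm counts, and inventing a test would overstate
the data. The summary reports the computed number of distinct toward-βIII
positions rather than hard-coding any published total (printed totals for
this quantity disagree with each other; the bundled patient fixture yields
13 distinct positions).

## Synthetic data

The generator emulates tubulin-like inputs: it starts from the bundled
reference (~450 aa, so any generated record is >90% identical to it at
default noise), imposes a planted residue profile at chosen canonical
positions, optionally splices insertions — the default test cohorts use
1–6-residue insertions, mirroring the 5–6-residue insertions real insect
β-tubulins carry in the 55–60 region — applies i.i.d. substitution noise
(off by default; the test cohorts use 0.02 per eligible position, comfortably
inside the >90% identity regime of real β-tubulins), and optionally replaces
the tail.
Noise never touches signature or motif positions unless the separate
`signature_noise_rate` is enabled (in which case the manifest is updated to
the post-noise truth). Seeding is one master seed with per-record derived
seeds, so cohorts are byte-reproducible.

The ground-truth manifest is computed at generation time, in canonical
coordinates, before insertions are spliced. Parameter-recovery tests then
demand *exact* equality between pipeline output and manifest. One boundary is
documented rather than hidden: gap placement at an insertion is inherently
ambiguous to any aligner when the residues flanking the insertion site
diverge from the reference, because a randomly inserted residue can mimic the
reference where the planted flank does not. Insertions in conserved stretches
are always recovered exactly (and the real insect insertions sit in conserved
context); test cohorts therefore place insertions away from divergent planted
signature positions, and the insertion stress test (lengths 1–10 at arbitrary
sites) runs on the unmodified reference backbone where recovery is
unconditional.

What passing synthetic tests do show: the numbering, extraction, counting,
motif, tail, and reporting machinery is exact under planted truth with
realistic indels and noise. What they do not show: anything about real
phylogenetic substitution processes (noise is i.i.d. by design, with no rate
matrix), about alignment of genuinely divergent families (identity floor
aside), or about the biology of the curated matrices themselves.

## Reporting and determinism

All reports are single-header TSV with rows in input order; cluster calls
print as Yes/No to diff directly against the published summary table.
Re-running any subcommand on identical inputs and configuration is
byte-identical. Output files are written atomically (temp file + rename), so
failed runs leave nothing partial behind. The acceptance script recomputes
the headline counts (Sepia isotype matches, the βV=βIII set and its
cancer-set overlap, chicken βVI matches) from the fixtures at run time; all
are desk-scale integer computations that finish in well under a second.

## Known limitations

- Numbering is strictly pairwise against one reference; sequences with
  large-scale rearrangements relative to βIII are out of scope.
- The printed matrices contain a handful of internal inconsistencies with
  their own summary table (Sepia isotype 2's universal-8 column, Lymnaea
  isotype 2's universal-8 column, one Drosophila isotype's all-25 column, the
  chicken βVI row, the Arabidopsis subset columns, and the βIII residue at
  189). The package reports what the matrices imply and does not chase the
  summary's printed values; tests assert only the self-consistent rows.
- No statistical test of convergence is offered (no permutation null): the
  quantitative surface is raw counts, and significance claims would require
  modeling choices the data do not constrain.
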